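# ViT-Large/16 encoder architecture (accounting only; no weights exist here).
[vit]
image_size = 224
patch_size = 16
in_channels = 3
embed_dim = 1024
depth = 24
num_heads = 16
mlp_ratio = 4
has_cls_token = true
learned_pos_embed = true
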