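"""End-to-end experiment orchestration.

One plain-text (TOML) config plus one integer seed fully determines every
artifact: the synthetic cohort, the Monte-Carlo splits, all training runs and
the statistical comparisons. Stage seeds derive from the global seed through
labelled :class:`numpy.random.SeedSequence` children (see :func:`derive_seed`),
so reruns are bit-identical.
"""

from __future__ import annotations

import json
import sys
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort, CohortSpec, PRESETS, generate_cohort
from .network import SplitPlan, build_network, monte_carlo_split
from .stats import compare_strategies, rag_analysis
from .training import RetinalAgeModel, TrainingProtocol, evaluate

__all__ = [
    "RunConfig",
    "ConfigError",
    "derive_seed",
    "validate_config",
    "load_config",
    "run_experiment",
]

# fixed stage labels for seed derivation
_STAGE = {"cohort": 0, "split": 1, "train": 2, "stats": 3}


def derive_seed(global_seed: int, stage: str, *extra: int) -> int:
    """Deterministic per-stage seed below 2**31.

    The derivation is ``SeedSequence([global_seed, stage_code, *extra])`` with
    stage codes cohort=0, split=1, train=2, stats=3; extras identify the
    iteration / size / strategy.
    """
    ss = np.random.SeedSequence([int(global_seed), _STAGE[stage], *map(int, extra)])
    return int(ss.generate_state(1)[0] % (2**31))


class ConfigError(ValueError):
    """Config file invalid; message lists every violation found."""


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "runs/experiment"
    cohort: CohortSpec = field(default_factory=lambda: PRESETS["ukb_like"])
    quantize_bits: int = 8  # 0 disables feature quantization
    n_train_sizes: tuple[int, ...] = (150, 300, 600, 1200, 2400)
    strategies: tuple[str, ...] = ("central", "fl", "tm")
    split: SplitPlan = field(default_factory=lambda: SplitPlan(n_train=2400))
    protocol: TrainingProtocol = field(default_factory=TrainingProtocol)
    stats_bin_width: float = 5.0
    stats_B: int = 10_000
    stats_alpha: float = 0.05
    n_comparisons_mae: int = 15
    n_comparisons_rag: int = 6


_TOP_KEYS = {"schema", "seed", "out_dir", "cohort", "split", "protocol", "stats"}
_COHORT_KEYS = {
    "preset", "n_subjects", "feature_dim", "age_mean", "age_sd", "age_min", "age_max",
    "n_centers", "signal_strength", "nonlinearity_coef", "site_sd", "eye_sd", "noise_sd",
    "disease_fraction", "disease_offset", "quantize_bits",
}
_SPLIT_KEYS = {"n_train", "n_val", "train_centers", "test_centers", "mc_iterations"}
_PROTOCOL_KEYS = {
    "strategies", "max_rounds", "patience", "fl_clients_per_round", "local_epochs",
    "batch_size_central", "lr", "weight_decay", "tm_carry_adam",
}
_STATS_KEYS = {"bin_width", "B", "alpha", "n_comparisons_mae", "n_comparisons_rag"}


def load_config(path) -> RunConfig:
    """Parse and strictly validate a TOML run config."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    return validate_config(raw)


def validate_config(raw: dict) -> RunConfig:
    """Cross-field validation collecting *all* violations before raising."""
    errors: list[str] = []

    def unknown(section: str, keys, allowed) -> None:
        extra = set(keys) - allowed
        if extra:
            errors.append(f"unknown key(s) in [{section}]: {sorted(extra)}")

    unknown("top level", raw.keys(), _TOP_KEYS)
    cohort_raw = dict(raw.get("cohort", {}))
    split_raw = dict(raw.get("split", {}))
    proto_raw = dict(raw.get("protocol", {}))
    stats_raw = dict(raw.get("stats", {}))
    unknown("cohort", cohort_raw.keys(), _COHORT_KEYS)
    unknown("split", split_raw.keys(), _SPLIT_KEYS)
    unknown("protocol", proto_raw.keys(), _PROTOCOL_KEYS)
    unknown("stats", stats_raw.keys(), _STATS_KEYS)

    quantize_bits = int(cohort_raw.pop("quantize_bits", 8))
    preset = cohort_raw.pop("preset", "ukb_like")
    if preset not in PRESETS:
        errors.append(f"cohort.preset must be one of {sorted(PRESETS)}, got {preset!r}")
        preset = "ukb_like"
    known = {k: v for k, v in cohort_raw.items() if k in _COHORT_KEYS}
    try:
        spec = PRESETS[preset].with_(**known)
    except ValueError as exc:
        errors.append(f"cohort: {exc}")
        spec = PRESETS[preset]

    sizes = split_raw.pop("n_train", [150, 300, 600, 1200, 2400])
    if isinstance(sizes, int):
        sizes = [sizes]
    strategies = tuple(proto_raw.pop("strategies", ["central", "fl", "tm"]))
    for s in strategies:
        if s not in ("central", "fl", "tm"):
            errors.append(f"protocol.strategies entry {s!r} not in central/fl/tm")
    try:
        plan = SplitPlan(
            n_train=max(sizes),
            n_val=int(split_raw.get("n_val", 1200)),
            train_centers=frozenset(split_raw.get("train_centers", [0, 1, 2, 3, 4])),
            test_centers=frozenset(split_raw.get("test_centers", [5, 6, 7])),
            mc_iterations=int(split_raw.get("mc_iterations", 10)),
        )
    except ValueError as exc:
        errors.append(f"split: {exc}")
        plan = SplitPlan(n_train=2400)
    try:
        protocol = TrainingProtocol(**proto_raw)
    except (TypeError, ValueError) as exc:
        errors.append(f"protocol: {exc}")
        protocol = TrainingProtocol()

    # cross-field checks
    n_healthy = spec.n_subjects - int(round(spec.disease_fraction * spec.n_subjects))
    expected_train_pool = n_healthy * len(plan.train_centers) / spec.n_centers
    if max(sizes) + plan.n_val > expected_train_pool:
        errors.append(
            f"split.n_train={max(sizes)} + n_val={plan.n_val} likely exceeds the "
            f"~{int(expected_train_pool)} healthy training-center subjects of this cohort"
        )
    if "fl" in strategies and protocol.fl_clients_per_round > min(sizes):
        errors.append(
            f"protocol.fl_clients_per_round={protocol.fl_clients_per_round} exceeds the "
            f"smallest training size split.n_train={min(sizes)}"
        )
    if errors:
        raise ConfigError("invalid config:\n  - " + "\n  - ".join(errors))

    return RunConfig(
        seed=int(raw.get("seed", 0)),
        out_dir=str(raw.get("out_dir", "runs/experiment")),
        cohort=spec,
        quantize_bits=quantize_bits,
        n_train_sizes=tuple(int(n) for n in sizes),
        strategies=strategies,
        split=plan,
        protocol=protocol,
        stats_bin_width=float(stats_raw.get("bin_width", 5.0)),
        stats_B=int(stats_raw.get("B", 10_000)),
        stats_alpha=float(stats_raw.get("alpha", 0.05)),
        n_comparisons_mae=int(stats_raw.get("n_comparisons_mae", 15)),
        n_comparisons_rag=int(stats_raw.get("n_comparisons_rag", 6)),
    )


def _log(msg: str, quiet: bool) -> None:
    if not quiet:
        print(msg, file=sys.stderr)


def run_experiment(config: RunConfig, seed: int | None = None, quiet: bool = False) -> dict:
    """Run the full Monte-Carlo grid (iterations x sizes x strategies).

    Within one iteration all strategies and sizes share the same validation
    set, and smaller training sets are prefixes of the same client draw, so
    strategy comparisons are paired. Returns the JSON-serializable report.
    """
    seed = config.seed if seed is None else int(seed)
    spec = config.cohort.with_(seed=derive_seed(seed, "cohort"))
    _log(f"stage=cohort n_subjects={spec.n_subjects} quantize_bits={config.quantize_bits}", quiet)
    cohort = generate_cohort(spec)
    if config.quantize_bits:
        cohort = cohort.quantized(config.quantize_bits)
    clients = build_network(cohort)

    plan = SplitPlan(
        n_train=max(config.n_train_sizes),
        n_val=config.split.n_val,
        train_centers=config.split.train_centers,
        test_centers=config.split.test_centers,
        mc_iterations=config.split.mc_iterations,
        seed=derive_seed(seed, "split"),
    )
    rows = []
    for it in range(plan.mc_iterations):
        split = monte_carlo_split(clients, plan, it)
        ext_X = None
        if split.external_test:
            from .training import pool_clients

            ext_X, ext_y = pool_clients(split.external_test)
        for n_train in config.n_train_sizes:
            train_subset = split.train[:n_train]  # nested sizes: paired across sizes
            for strat_idx, strategy in enumerate(config.strategies):
                protocol = TrainingProtocol(
                    strategy=strategy,
                    max_rounds=config.protocol.max_rounds,
                    patience=config.protocol.patience,
                    fl_clients_per_round=config.protocol.fl_clients_per_round,
                    local_epochs=config.protocol.local_epochs,
                    batch_size_central=config.protocol.batch_size_central,
                    lr=config.protocol.lr,
                    weight_decay=config.protocol.weight_decay,
                    tm_carry_adam=config.protocol.tm_carry_adam,
                    seed=derive_seed(seed, "train", it, n_train, strat_idx),
                )
                model = RetinalAgeModel(train_subset, split.validation, protocol=protocol)
                try:
                    res = model.fit()
                except Exception as exc:
                    raise RuntimeError(
                        f"stage=train iteration={it} n_train={n_train} "
                        f"strategy={strategy}: {exc}"
                    ) from exc
                row = {
                    "iteration": it,
                    "n_train": n_train,
                    "strategy": strategy,
                    "val_mae": res.val_mae,
                    "external_mae": (
                        float(np.mean(np.abs(res.predict(ext_X) - ext_y)))
                        if ext_X is not None
                        else None
                    ),
                    "best_round": res.best_round,
                    "rounds_run": len(res.history),
                    "updates_per_client": res.updates_per_client,
                    "train_flops": res.ledger.train_flops,
                    "model_transfers": res.ledger.model_transfers,
                    "bytes_transferred": res.ledger.bytes_transferred,
                }
                rows.append(row)
                _log(
                    f"stage=train iteration={it} n_train={n_train} strategy={strategy} "
                    f"val_mae={res.val_mae:.3f} rounds={len(res.history)}",
                    quiet,
                )

    table = pd.DataFrame(rows)
    aggregates = []
    for (n_train, strategy), grp in table.groupby(["n_train", "strategy"]):
        aggregates.append(
            {
                "n_train": int(n_train),
                "strategy": strategy,
                "val_mae_mean": float(grp["val_mae"].mean()),
                "val_mae_std": float(grp["val_mae"].std(ddof=1)) if len(grp) > 1 else 0.0,
                "external_mae_mean": (
                    float(grp["external_mae"].mean())
                    if grp["external_mae"].notna().all()
                    else None
                ),
                "updates_per_client_mean": float(grp["updates_per_client"].mean()),
            }
        )
    comparisons = {}
    if len(config.strategies) >= 2 and plan.mc_iterations >= 2:
        for n_train, grp in table.groupby("n_train"):
            comparisons[str(int(n_train))] = compare_strategies(
                grp[["strategy", "iteration", "val_mae"]].rename(columns={"val_mae": "mae"}),
                alpha=config.stats_alpha,
                n_comparisons=config.n_comparisons_mae,
            )
    return {
        "schema": "fedgap-report-v1",
        "seed": seed,
        "n_train_sizes": list(config.n_train_sizes),
        "strategies": list(config.strategies),
        "mc_iterations": plan.mc_iterations,
        "quantize_bits": config.quantize_bits,
        "runs": rows,
        "aggregates": aggregates,
        "comparisons": comparisons,
    }


def save_report(report: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1)
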