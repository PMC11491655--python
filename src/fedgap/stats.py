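"""Retinal-age-gap (RAG) statistics.

RAG = predicted biological age minus chronological age, averaged over a
subject's two eyes. A trained head applied to a healthy population should give
mean RAG near zero; a disease group with accelerated retinal aging shows a
positive mean RAG. Because the head is trained on one age distribution and the
target groups follow another, group means are compared after importance
weighting: each target subject is weighted by the histogram ratio
``p_train(age bin) / p_target(age bin)``, and group means are compared with a
one-tailed weighted bootstrap test (H1: disease > healthy).

Strategy comparison (centralized vs federated vs traveling) uses paired
two-sided t-tests and one-way ANOVA over Monte-Carlo iterations, with
Bonferroni-corrected thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import Cohort, IntegrityError
from .heads import HeadModel, predict

__all__ = [
    "RAGReport",
    "compute_rag",
    "age_weights",
    "bootstrap_group_test",
    "bonferroni_alpha",
    "compare_strategies",
    "rag_analysis",
]


def compute_rag(head: HeadModel, cohort: Cohort) -> pd.DataFrame:
    """Per-subject RAG: mean of the two eye-level (prediction - age) gaps.

    Returns a frame with one row per subject: subject_id, group, age, rag.
    """
    gaps = predict(head, cohort.features) - cohort.meta["age"].to_numpy()
    df = cohort.meta.assign(gap=gaps)
    counts = df.groupby("subject_id", sort=False).size()
    if (counts != 2).any():  # pragma: no cover - Cohort validates on build
        raise IntegrityError("every subject needs both eyes for a RAG value")
    out = (
        df.groupby("subject_id", sort=False)
        .agg(group=("group", "first"), age=("age", "first"), rag=("gap", "mean"))
        .reset_index()
    )
    return out


def age_weights(
    train_ages: np.ndarray,
    target_ages: np.ndarray,
    bin_width: float = 5.0,
) -> np.ndarray:
    """Histogram-ratio importance weights aligning a target group's age
    distribution to the training distribution.

    Shared bin grid spanning both samples; weight of a target subject in bin b
    is ``p_train(b) / p_target(b)`` (0 where the training set has no support),
    renormalized to mean 1 over the target subjects.
    """
    train_ages = np.asarray(train_ages, dtype=float)
    target_ages = np.asarray(target_ages, dtype=float)
    if train_ages.size == 0 or target_ages.size == 0:
        raise ValueError("both age samples must be non-empty")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo = min(train_ages.min(), target_ages.min())
    hi = max(train_ages.max(), target_ages.max())
    edges = np.arange(lo, hi + bin_width, bin_width)
    if edges[-1] <= hi:
        edges = np.append(edges, edges[-1] + bin_width)
    p_train, _ = np.histogram(train_ages, bins=edges)
    p_target, _ = np.histogram(target_ages, bins=edges)
    idx = np.clip(np.digitize(target_ages, edges) - 1, 0, len(edges) - 2)
    ratio = np.zeros(len(edges) - 1)
    occupied = p_target > 0  # empty-target-bin guard (no subject falls there)
    ratio[occupied] = (p_train[occupied] / p_train.sum()) / (p_target[occupied] / p_target.sum())
    w = ratio[idx]
    if not np.any(w > 0):
        raise ValueError("degenerate support: train and target age ranges do not overlap")
    return w / w.mean()


def bootstrap_group_test(
    rag_disease: np.ndarray,
    rag_healthy: np.ndarray,
    weights_d: np.ndarray | None = None,
    weights_h: np.ndarray | None = None,
    B: int = 10_000,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """One-tailed weighted bootstrap test of mean(disease) > mean(healthy).

    Each replicate resamples subjects with replacement within each group with
    selection probability proportional to the importance weights, and records
    mean(disease) - mean(healthy). p = (1 + #{replicates <= 0}) / (B + 1).
    """
    rag_disease = np.asarray(rag_disease, dtype=float)
    rag_healthy = np.asarray(rag_healthy, dtype=float)
    if len(rag_disease) < 2 or len(rag_healthy) < 2:
        raise ValueError("each group needs at least 2 subjects")
    if B < 1:
        raise ValueError("B must be >= 1")

    def _probs(w, n):
        if w is None:
            return None  # uniform resampling
        w = np.asarray(w, dtype=float)
        if w.shape != (n,) or (w < 0).any() or not np.isfinite(w).all():
            raise ValueError("weights must be non-negative, finite, one per subject")
        return w / w.sum()

    p_d = _probs(weights_d, len(rag_disease))
    p_h = _probs(weights_h, len(rag_healthy))
    rng = np.random.default_rng(seed)
    idx_d = rng.choice(len(rag_disease), size=(B, len(rag_disease)), p=p_d)
    idx_h = rng.choice(len(rag_healthy), size=(B, len(rag_healthy)), p=p_h)
    diffs = rag_disease[idx_d].mean(axis=1) - rag_healthy[idx_h].mean(axis=1)
    p_value = (1.0 + np.count_nonzero(diffs <= 0.0)) / (B + 1.0)
    return float(p_value), diffs


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Bonferroni-corrected significance threshold alpha / m."""
    if m < 1:
        raise ValueError("number of comparisons m must be >= 1")
    return alpha / m


@dataclass
class RAGReport:
    """Weighted group comparison of RAG values."""

    rag_disease: np.ndarray
    rag_healthy: np.ndarray
    weights_disease: np.ndarray
    weights_healthy: np.ndarray
    mean_disease: float
    mean_healthy: float
    p_value: float
    alpha_corrected: float
    replicate_diffs: np.ndarray
    B: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "schema": "fedgap-rag-v1",
            "mean_rag_disease": self.mean_disease,
            "mean_rag_healthy": self.mean_healthy,
            "p_value": self.p_value,
            "alpha_corrected": self.alpha_corrected,
            "B": self.B,
            "seed": self.seed,
            "n_disease": int(len(self.rag_disease)),
            "n_healthy": int(len(self.rag_healthy)),
            "rag_disease": self.rag_disease.tolist(),
            "rag_healthy": self.rag_healthy.tolist(),
            "weights_disease": self.weights_disease.tolist(),
            "weights_healthy": self.weights_healthy.tolist(),
        }


def rag_analysis(
    head: HeadModel,
    target_cohort: Cohort,
    train_ages: np.ndarray,
    bin_width: float = 5.0,
    B: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
    n_comparisons: int = 6,
) -> RAGReport:
    """End-to-end RAG comparison on one target cohort.

    Computes per-subject RAG for the healthy and disease groups, importance
    weights against the training age distribution, weighted group means and
    the one-tailed bootstrap p-value at the Bonferroni-corrected threshold.
    """
    per_subject = compute_rag(head, target_cohort)
    dis = per_subject[per_subject["group"] == "disease"]
    hea = per_subject[per_subject["group"] == "healthy"]
    if len(dis) < 2 or len(hea) < 2:
        raise ValueError("target cohort needs >= 2 subjects in each group")
    w_d = age_weights(train_ages, dis["age"].to_numpy(), bin_width)
    w_h = age_weights(train_ages, hea["age"].to_numpy(), bin_width)
    rag_d = dis["rag"].to_numpy()
    rag_h = hea["rag"].to_numpy()
    p, diffs = bootstrap_group_test(rag_d, rag_h, w_d, w_h, B=B, seed=seed)
    return RAGReport(
        rag_disease=rag_d,
        rag_healthy=rag_h,
        weights_disease=w_d,
        weights_healthy=w_h,
        mean_disease=float(np.average(rag_d, weights=w_d)),
        mean_healthy=float(np.average(rag_h, weights=w_h)),
        p_value=p,
        alpha_corrected=bonferroni_alpha(alpha, n_comparisons),
        replicate_diffs=diffs,
        B=B,
        seed=seed,
    )


def _pairwise_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided pooled-variance t-test, defined as (0, 1) for identical data."""
    if np.allclose(np.asarray(a, dtype=float), np.asarray(b, dtype=float)):
        return 0.0, 1.0
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def compare_strategies(
    mae_table: pd.DataFrame,
    alpha: float = 0.05,
    n_comparisons: int = 15,
) -> dict:
    """Compare strategies' MAE across paired Monte-Carlo iterations.

    ``mae_table`` needs columns ``strategy``, ``iteration``, ``mae`` with every
    strategy measured on the same iterations. Returns per-strategy ``mean ±
    std`` summaries, pairwise two-sided pooled-variance t-tests (the standard
    analysis for Monte-Carlo MAE tables, even though iterations share splits),
    a one-way ANOVA F test and the Bonferroni-corrected threshold.
    """
    required = {"strategy", "iteration", "mae"}
    if not required <= set(mae_table.columns):
        raise ValueError(f"mae_table needs columns {sorted(required)}")
    wide = mae_table.pivot(index="iteration", columns="strategy", values="mae")
    if wide.isna().any().any():
        raise ValueError("unpaired iterations: every strategy needs every iteration")
    strategies = list(wide.columns)
    summary = {
        s: {
            "mean": float(wide[s].mean()),
            "std": float(wide[s].std(ddof=1)),
            "formatted": f"{wide[s].mean():.2f} ± {wide[s].std(ddof=1):.2f}",
        }
        for s in strategies
    }
    pairwise = {}
    for i, a in enumerate(strategies):
        for b in strategies[i + 1 :]:
            t, p = _pairwise_t(wide[a].to_numpy(), wide[b].to_numpy())
            pairwise[f"{a}_vs_{b}"] = {"t": t, "p": p}
    if len(strategies) >= 2:
        groups = [wide[s].to_numpy() for s in strategies]
        if all(np.allclose(g, groups[0]) for g in groups):
            anova = {"F": 0.0, "p": 1.0}
        else:
            F, p = sps.f_oneway(*groups)
            anova = {"F": float(F), "p": float(p)}
    else:
        anova = {"F": float("nan"), "p": float("nan")}
    return {
        "summary": summary,
        "pairwise_t": pairwise,
        "anova": anova,
        "alpha_corrected": bonferroni_alpha(alpha, n_comparisons),
        "n_iterations": int(len(wide)),
    }
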