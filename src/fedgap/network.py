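"""One-subject-per-client network and Monte-Carlo cross-validation splits.

Every subject's two eye records live on their own simulated client (think: a
personal phone holding two fundus-derived feature vectors). Splits assign
healthy clients from the training centers to train/validation roles by
seeded sampling without replacement; healthy clients at the held-out centers
are the external test set. Disease clients never receive a role — they are
the target group of the age-gap analysis, not training material.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .cohort import Cohort, IntegrityError

__all__ = ["Client", "SplitPlan", "SplitAssignment", "build_network", "monte_carlo_split"]


class CapacityError(ValueError):
    """Requested split sizes exceed the eligible client pool."""


@dataclass
class Client:
    """One subject's data: a (2, D) feature block and two equal ages."""

    client_id: str
    X: np.ndarray  # (2, feature_dim), rows L then R
    y: np.ndarray  # (2,) chronological age (both rows equal)
    center_id: int
    group: str

    @property
    def age(self) -> float:
        return float(self.y[0])


def build_network(cohort: Cohort) -> list[Client]:
    """One client per subject, in subject-id order (input-order invariant)."""
    meta = cohort.meta
    order = np.lexsort((meta["eye"].to_numpy(), meta["subject_id"].to_numpy()))
    clients: list[Client] = []
    sid = meta["subject_id"].to_numpy()[order]
    for start in range(0, len(order), 2):
        i, j = order[start], order[start + 1]
        if sid[start] != sid[start + 1]:  # pragma: no cover - Cohort validates
            raise IntegrityError(f"subject {sid[start]} lacks an L/R pair")
        row_i, row_j = meta.iloc[i], meta.iloc[j]
        clients.append(
            Client(
                client_id=str(row_i["subject_id"]),
                X=np.stack([cohort.features[i], cohort.features[j]]),
                y=np.array([float(row_i["age"]), float(row_j["age"])]),
                center_id=int(row_i["center"]),
                group=str(row_i["group"]),
            )
        )
    return clients


@dataclass(frozen=True)
class SplitPlan:
    """Monte-Carlo split sizes and the center partition."""

    n_train: int
    n_val: int = 1200
    train_centers: frozenset[int] = frozenset({0, 1, 2, 3, 4})
    test_centers: frozenset[int] = frozenset({5, 6, 7})
    mc_iterations: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_train < 1 or self.n_val < 1:
            raise ValueError("n_train and n_val must be >= 1")
        if set(self.train_centers) & set(self.test_centers):
            raise ValueError("train_centers and test_centers overlap")
        object.__setattr__(self, "train_centers", frozenset(self.train_centers))
        object.__setattr__(self, "test_centers", frozenset(self.test_centers))


@dataclass
class SplitAssignment:
    """Role assignment for one Monte-Carlo iteration (disjoint by subject)."""

    iteration: int
    train: list[Client]
    validation: list[Client]
    external_test: list[Client]

    def manifest(self) -> dict:
        return {
            "iteration": self.iteration,
            "train": [c.client_id for c in self.train],
            "validation": [c.client_id for c in self.validation],
            "external_test": [c.client_id for c in self.external_test],
        }

    def save_manifest(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.manifest(), fh, indent=1)


def monte_carlo_split(
    clients: list[Client], plan: SplitPlan, iteration: int
) -> SplitAssignment:
    """Deterministic role draw for one iteration.

    Validation clients are sampled first, then training clients from the
    remainder, both without replacement from healthy clients at the training
    centers. All healthy clients at test centers become the external test set.
    """
    if not 0 <= iteration:
        raise ValueError("iteration must be >= 0")
    eligible = [c for c in clients if c.group == "healthy" and c.center_id in plan.train_centers]
    external = [c for c in clients if c.group == "healthy" and c.center_id in plan.test_centers]
    need = plan.n_train + plan.n_val
    if need > len(eligible):
        raise CapacityError(
            f"n_train+n_val = {need} exceeds the {len(eligible)} healthy clients "
            f"at training centers"
        )
    rng = np.random.default_rng(np.random.SeedSequence([plan.seed, iteration]))
    eligible = sorted(eligible, key=lambda c: c.client_id)  # input-order invariance
    picked = rng.choice(len(eligible), size=need, replace=False)
    val = [eligible[i] for i in picked[: plan.n_val]]
    train = [eligible[i] for i in picked[plan.n_val :]]
    return SplitAssignment(
        iteration=iteration,
        train=train,
        validation=val,
        external_test=sorted(external, key=lambda c: c.client_id),
    )
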