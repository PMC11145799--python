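"""Analysis weights: crude, overlap weighting, fine stratification, pruning.

Seven method labels are used throughout the pipeline: ``crude``, ``OW_F``,
``OW_X``, ``FS_F_equ``, ``FS_X_equ``, ``FS_F_unequ``, ``FS_X_unequ`` —
overlap weights and fine-stratification weights on the full (F) or
cross-classification-pruned (X) dataset, FS with either of the two
average-treatment-effect weighting schemes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort
from .exceptions import PruningError, StratificationError
from .propensity import PSFit

METHODS = ("crude", "OW_F", "OW_X", "FS_F_equ", "FS_X_equ", "FS_F_unequ", "FS_X_unequ")
FS_SCHEMES = ("equ", "unequ")


@dataclass
class WeightAssignment:
    """Per-subject analysis weights with an inclusion mask."""

    method_label: str
    weights: np.ndarray
    included: np.ndarray
    stratum_id: np.ndarray | None = None

    @property
    def n_used(self) -> int:
        return int(self.included.sum())

    def to_frame(self, cohort: Cohort) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "subject_id": cohort.subject_id,
                "method_label": self.method_label,
                "weight": self.weights,
                "included": self.included,
            }
        )
        if self.stratum_id is not None:
            frame["stratum_id"] = self.stratum_id
        return frame


@dataclass
class Stratification:
    """Equal-frequency PS strata built on the exposed group's score distribution."""

    boundaries: np.ndarray  # K+1 ascending cut points
    stratum_id: np.ndarray  # per subject; -1 = excluded (non-overlap or dropped stratum)
    n_total: np.ndarray  # per stratum, retained-or-not
    n_exposed: np.ndarray
    n_unexposed: np.ndarray
    retained: np.ndarray  # per stratum bool
    excluded_nonoverlap: int

    @property
    def included(self) -> np.ndarray:
        return self.stratum_id >= 0


def crude_weights(cohort: Cohort, label: str = "crude") -> WeightAssignment:
    """Unit weights on the dataset as given — no PS involvement."""
    return WeightAssignment(label, np.ones(cohort.n), np.ones(cohort.n, dtype=bool))


def overlap_weights(fit: PSFit, cohort: Cohort, label: str = "OW_F") -> WeightAssignment:
    """Treated get 1 - PS, controls get PS; nobody is pruned."""
    z = cohort.exposure.astype(bool)
    weights = np.where(z, 1.0 - fit.scores, fit.scores)
    return WeightAssignment(label, weights, np.ones(cohort.n, dtype=bool))


def fine_stratify(fit: PSFit, cohort: Cohort, k_strata: int = 20) -> Stratification:
    """Equal-frequency strata from the exposed group's PS quantiles.

    Controls strictly outside the exposed PS range are excluded as
    non-overlap.  Subjects at an internal boundary go to the lower stratum.
    Strata lacking a subject from either group are dropped and their
    members excluded.
    """
    z = cohort.exposure.astype(bool)
    scores = np.asarray(fit.scores, dtype=float)
    exposed_scores = scores[z]
    if exposed_scores.size < k_strata:
        raise StratificationError(
            f"only {exposed_scores.size} exposed subjects for {k_strata} strata; use a smaller k"
        )
    boundaries = np.quantile(exposed_scores, np.linspace(0.0, 1.0, k_strata + 1))

    stratum = np.searchsorted(boundaries[1:-1], scores, side="left").astype(int)
    nonoverlap = (~z) & ((scores < boundaries[0]) | (scores > boundaries[-1]))
    stratum[nonoverlap] = -1
    excluded_nonoverlap = int(nonoverlap.sum())

    n_exposed = np.bincount(stratum[z & (stratum >= 0)], minlength=k_strata)
    n_unexposed = np.bincount(stratum[~z & (stratum >= 0)], minlength=k_strata)
    retained = (n_exposed >= 1) & (n_unexposed >= 1)
    dropped = (stratum >= 0) & ~retained[np.clip(stratum, 0, k_strata - 1)]
    stratum[dropped] = -1
    return Stratification(
        boundaries=boundaries,
        stratum_id=stratum,
        n_total=n_exposed + n_unexposed,
        n_exposed=n_exposed,
        n_unexposed=n_unexposed,
        retained=retained,
        excluded_nonoverlap=excluded_nonoverlap,
    )


def fs_weights(
    strat: Stratification, cohort: Cohort, scheme: str, label: str | None = None
) -> WeightAssignment:
    """Stratum-level ATE weights.

    ``equ`` gives stratum weights N_i/N_exp_i (exposed) and N_i/N_unexp_i
    (unexposed), so both groups' weight totals equal the retained N.
    ``unequ`` rescales by the retained group totals, (N_i/N)/(N_exp_i/N_exp)
    and (N_i/N)/(N_unexp_i/N_unexp), so each group's weight total equals its
    retained size.  Totals are computed over retained strata only.
    """
    if scheme not in FS_SCHEMES:
        raise ValueError(f"unknown FS scheme {scheme!r}; expected one of {FS_SCHEMES}")
    if not strat.retained.any():
        raise StratificationError("no retained strata")
    z = cohort.exposure.astype(bool)
    included = strat.included
    n_i = strat.n_total.astype(float)
    n_exp_i = strat.n_exposed.astype(float)
    n_unexp_i = strat.n_unexposed.astype(float)

    with np.errstate(divide="ignore", invalid="ignore"):
        w_exp = n_i / n_exp_i
        w_unexp = n_i / n_unexp_i
        if scheme == "unequ":
            n_tot = n_i[strat.retained].sum()
            n_exp = n_exp_i[strat.retained].sum()
            n_unexp = n_unexp_i[strat.retained].sum()
            w_exp = (n_i / n_tot) / (n_exp_i / n_exp)
            w_unexp = (n_i / n_tot) / (n_unexp_i / n_unexp)

    weights = np.zeros(cohort.n)
    sid = np.clip(strat.stratum_id, 0, len(n_i) - 1)
    weights[included & z] = w_exp[sid[included & z]]
    weights[included & ~z] = w_unexp[sid[included & ~z]]
    return WeightAssignment(
        label or f"FS_{scheme}",
        weights,
        included.copy(),
        stratum_id=strat.stratum_id.copy(),
    )


def prune_unmatched(cohort: Cohort, binary_names: list[str] | None = None) -> Cohort:
    """Drop subjects whose binary-covariate cross-classification cell holds only one group.

    This is the 'X' dataset: every retained cell of the joint binary
    covariate table contains at least one exposed and one unexposed subject.
    Idempotent.
    """
    names = binary_names if binary_names is not None else cohort.binary_names
    for name in names:
        col = cohort.data[name]
        if not set(np.unique(col)) <= {0, 1}:
            raise ValueError(f"column {name!r} is not 0/1")
    both = cohort.data.groupby(names, sort=False)["exposure"].transform("nunique") == 2
    if not both.any():
        raise PruningError("every cross-classification cell is single-group; nothing left")
    return cohort.subset(both.to_numpy())
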