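"""SL/SR genetic-interaction matching score (EMS).

Given a drug's genetic-interaction network — synthetic-lethal (SL) partners
of the drug targets, whose joint inactivation with the target kills the
tumor cell, and synthetic-rescue (SR) partners, whose activation compensates
for target loss — a tumor is a good match for the drug when many SL partners
are lowly expressed and few SR rescuers are highly expressed.

The score used here: expression is rank-normalized per gene across the
cohort to [0, 1]; an SL partner counts as favorable when its rank falls in
the bottom tertile (<= 1/3), an SR partner when it is *not* in the top
tertile (< 2/3); EMS is the favorable fraction over the partners present in
the matrix, so EMS is always in [0, 1] and invariant to monotone per-gene
transformations.  A patient is called matched when EMS >= 0.54, the fixed
clinical decision threshold.  Target-gene expression itself is never
consulted (the monoclonal-antibody target-expression component is excluded,
as it over-weighs a single, possibly noisily imputed gene).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .expr_prep import ExpressionMatrix

__all__ = [
    "GINetwork",
    "EMSResult",
    "rank_normalize_cohort",
    "compute_ems",
    "score_cohort",
    "EMS_THRESHOLD",
    "SL_ACTIVE_MAX_RANK",
    "SR_INACTIVE_MAX_RANK",
]

EMS_THRESHOLD = 0.54
SL_ACTIVE_MAX_RANK = 1.0 / 3.0   # SL partner favorable: bottom tertile (inclusive)
SR_INACTIVE_MAX_RANK = 2.0 / 3.0  # SR partner favorable: below the top tertile (strict)


@dataclass
class GINetwork:
    """Drug target(s) plus SL and SR partner gene lists."""

    drug: str
    targets: list[str]
    sl_partners: list[str]
    sr_partners: list[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        if set(self.sl_partners) & set(self.sr_partners):
            raise ValueError("SL and SR partner lists must be disjoint")
        if not self.sl_partners and not self.sr_partners:
            raise ValueError("network has no partners")

    @classmethod
    def from_json(cls, path) -> "GINetwork":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            drug=d["drug"], targets=list(d.get("targets", [])),
            sl_partners=list(d.get("sl_partners", [])),
            sr_partners=list(d.get("sr_partners", [])),
            provenance=d.get("provenance", ""),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"drug": self.drug, "targets": self.targets,
                 "sl_partners": self.sl_partners, "sr_partners": self.sr_partners,
                 "provenance": self.provenance},
                fh, indent=2,
            )


@dataclass
class EMSResult:
    patient_id: str
    ems: float
    matched: bool
    threshold: float = EMS_THRESHOLD
    n_partners_present: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.ems <= 1.0:
            raise ValueError("EMS must lie in [0, 1]")


def rank_normalize_cohort(expr: ExpressionMatrix | pd.DataFrame) -> pd.DataFrame:
    """Per-gene patient ranks in [0, 1] (average ties, (rank-1)/(n-1))."""
    v = expr.values if isinstance(expr, ExpressionMatrix) else expr
    n = v.shape[1]
    if n < 3:
        raise ValueError("need at least 3 patients for a rank reference distribution")
    ranks = np.apply_along_axis(rankdata, 1, v.to_numpy(dtype=float))
    return pd.DataFrame((ranks - 1.0) / (n - 1.0), index=v.index, columns=v.columns)


def compute_ems(
    patient_ranks: pd.Series, network: GINetwork, threshold: float = EMS_THRESHOLD
) -> EMSResult:
    """EMS of one patient from their per-gene normalized ranks.

    EMS = [#{SL partners with rank <= 1/3} + #{SR partners with rank < 2/3}]
    over the number of partners present in the profile.  Partners absent
    from the profile are excluded from numerator and denominator; the drug
    target genes are never used.
    """
    sl = [g for g in network.sl_partners if g in patient_ranks.index]
    sr = [g for g in network.sr_partners if g in patient_ranks.index]
    n_present = len(sl) + len(sr)
    if n_present == 0:
        raise ValueError(
            f"no partner of network {network.drug!r} present in the expression matrix"
        )
    favorable = int(np.sum(patient_ranks[sl].to_numpy() <= SL_ACTIVE_MAX_RANK))
    favorable += int(np.sum(patient_ranks[sr].to_numpy() < SR_INACTIVE_MAX_RANK))
    ems = favorable / n_present
    return EMSResult(
        patient_id=str(patient_ranks.name), ems=float(ems),
        matched=bool(ems >= threshold), threshold=threshold,
        n_partners_present=n_present,
    )


def score_cohort(
    expr: ExpressionMatrix | pd.DataFrame,
    network: GINetwork,
    threshold: float = EMS_THRESHOLD,
    reference: ExpressionMatrix | pd.DataFrame | None = None,
) -> list[EMSResult]:
    """One EMSResult per patient of a cohort.

    The activation reference is the cohort's own rank distribution; pass an
    external ``reference`` matrix (same genes) to rank each patient against
    it instead, which also enables single-patient scoring.
    """
    v = expr.values if isinstance(expr, ExpressionMatrix) else expr
    if reference is None:
        ranks = rank_normalize_cohort(v)
    else:
        ref = reference.values if isinstance(reference, ExpressionMatrix) else reference
        nref = ref.shape[1]
        if nref < 3:
            raise ValueError("reference cohort must have at least 3 patients")
        cols = {}
        refv = ref.loc[v.index].to_numpy(dtype=float)
        for patient in v.columns:
            x = v[patient].to_numpy(dtype=float)
            # fraction of reference patients strictly below, ties half-weighted
            below = (refv < x[:, None]).sum(axis=1) + 0.5 * (refv == x[:, None]).sum(axis=1)
            cols[patient] = below / nref
        ranks = pd.DataFrame(cols, index=v.index)
    return [compute_ems(ranks[p], network, threshold) for p in ranks.columns]


def ems_frame(results: list[EMSResult]) -> pd.DataFrame:
    """Tabular view of a list of EMS results."""
    return pd.DataFrame(
        {"patient_id": [r.patient_id for r in results],
         "ems": [r.ems for r in results],
         "matched": [r.matched for r in results]}
    ).set_index("patient_id")
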