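"""Two-timepoint stable DEG signature: intersection plus filter cascade.

A gene enters the stable signature when it is called differentially
expressed in the same direction at both timepoints (|log2FC| > 0.6 and
q < 0.1, both strict, at each timepoint) and then survives two further
filters: posterior DE probability >= 0.75 at at least one timepoint, and
linear fold change >= 1.5 at both timepoints. Hub selection among the up
genes and up/down pairing are separate stages (see ``network`` and
``ratio``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .diffexp import DEGTable

FC_LOG2_MIN = 0.6
Q_MAX = 0.1
LINEAR_FC_MIN = 1.5
B_POSTERIOR_MIN = 0.75


@dataclass
class SignatureSet:
    """Stable up/down marker genes with filter provenance."""

    up_genes: list[str]
    down_genes: list[str]
    provenance: pd.DataFrame  # per-gene stats at both timepoints + filter flags
    dropped_sign_conflicts: list[str] = field(default_factory=list)
    fc_log2_min: float = FC_LOG2_MIN
    q_max: float = Q_MAX
    linear_fc_min: float = LINEAR_FC_MIN
    b_posterior_min: float = B_POSTERIOR_MIN

    def __post_init__(self) -> None:
        if set(self.up_genes) & set(self.down_genes):
            raise ValueError("up and down gene sets must be disjoint")

    @property
    def genes(self) -> list[str]:
        return self.up_genes + self.down_genes


def select_degs(
    deg: DEGTable, fc_log2_min: float = FC_LOG2_MIN, q_max: float = Q_MAX
) -> pd.Series:
    """DEG call at one timepoint: |log2FC| > fc_log2_min and q < q_max (strict).

    Returns the signed direction (+1 up in non-survivors, -1 down) indexed by
    the selected gene ids.
    """
    if fc_log2_min <= 0 or q_max <= 0:
        raise ValueError("thresholds must be positive")
    t = deg.table
    keep = (t["log2_fc"].abs() > fc_log2_min) & (t["q"] < q_max)
    signs = t.loc[keep, "log2_fc"].apply(lambda v: 1 if v > 0 else -1)
    return signs.astype(int)


def intersect_timepoints(
    set_d1: pd.Series, set_d23: pd.Series
) -> tuple[pd.Series, list[str]]:
    """Genes selected at both timepoints with consistent direction.

    Returns (signed stable set, list of genes dropped for sign conflict).
    """
    common = set_d1.index.intersection(set_d23.index)
    same = [g for g in common if set_d1[g] == set_d23[g]]
    conflicts = [g for g in common if set_d1[g] != set_d23[g]]
    return set_d1.loc[same], conflicts


def apply_filter_cascade(
    stable: pd.Series,
    deg_d1: DEGTable,
    deg_d23: DEGTable,
    linear_fc_min: float = LINEAR_FC_MIN,
    b_posterior_min: float = B_POSTERIOR_MIN,
    fc_log2_min: float = FC_LOG2_MIN,
    q_max: float = Q_MAX,
) -> SignatureSet:
    """Retain stable genes passing the posterior-probability and linear-FC filters.

    A gene survives when posterior_prob >= b_posterior_min at >= 1 timepoint
    (non-strict) and 2^|log2FC| >= linear_fc_min at BOTH timepoints
    (non-strict), then is partitioned by direction: up = higher in
    non-survivors.
    """
    missing = [
        g
        for g in stable.index
        if g not in deg_d1.table.index or g not in deg_d23.table.index
    ]
    if missing:
        raise KeyError(f"stable genes missing from a DEG table: {missing}")

    rows = []
    up, down = [], []
    for g in stable.index:
        r1, r23 = deg_d1.table.loc[g], deg_d23.table.loc[g]
        lin1, lin23 = 2.0 ** abs(r1["log2_fc"]), 2.0 ** abs(r23["log2_fc"])
        pass_b = (
            r1["posterior_prob"] >= b_posterior_min
            or r23["posterior_prob"] >= b_posterior_min
        )
        pass_fc = lin1 >= linear_fc_min and lin23 >= linear_fc_min
        rows.append(
            {
                "gene": g,
                "sign": int(stable[g]),
                "log2_fc_d1": r1["log2_fc"],
                "log2_fc_d23": r23["log2_fc"],
                "q_d1": r1["q"],
                "q_d23": r23["q"],
                "posterior_d1": r1["posterior_prob"],
                "posterior_d23": r23["posterior_prob"],
                "pass_posterior": bool(pass_b),
                "pass_linear_fc": bool(pass_fc),
                "in_signature": bool(pass_b and pass_fc),
            }
        )
        if pass_b and pass_fc:
            (up if stable[g] > 0 else down).append(g)

    provenance = pd.DataFrame(rows).set_index("gene") if rows else pd.DataFrame(
        columns=[
            "sign",
            "log2_fc_d1",
            "log2_fc_d23",
            "q_d1",
            "q_d23",
            "posterior_d1",
            "posterior_d23",
            "pass_posterior",
            "pass_linear_fc",
            "in_signature",
        ]
    )
    return SignatureSet(
        up_genes=sorted(up),
        down_genes=sorted(down),
        provenance=provenance,
        linear_fc_min=linear_fc_min,
        b_posterior_min=b_posterior_min,
        fc_log2_min=fc_log2_min,
        q_max=q_max,
    )


def build_signature(
    deg_d1: DEGTable,
    deg_d23: DEGTable,
    fc_log2_min: float = FC_LOG2_MIN,
    q_max: float = Q_MAX,
    linear_fc_min: float = LINEAR_FC_MIN,
    b_posterior_min: float = B_POSTERIOR_MIN,
) -> SignatureSet:
    """DEG call at both timepoints, intersection, and filter cascade."""
    s1 = select_degs(deg_d1, fc_log2_min, q_max)
    s23 = select_degs(deg_d23, fc_log2_min, q_max)
    stable, conflicts = intersect_timepoints(s1, s23)
    sig = apply_filter_cascade(
        stable,
        deg_d1,
        deg_d23,
        linear_fc_min=linear_fc_min,
        b_posterior_min=b_posterior_min,
        fc_log2_min=fc_log2_min,
        q_max=q_max,
    )
    sig.dropped_sign_conflicts = conflicts
    return sig
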