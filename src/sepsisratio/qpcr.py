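"""Efficiency-corrected relative quantification from RT-qPCR Cq tables.

Standard curves (Cq vs log10 relative template quantity) give each gene's
amplification efficiency E = 10^(-1/slope); unknowns are quantified as
E^(Cq_cal - Cq) or by inverting the curve, technical replicates are
averaged on the Cq scale, and per-plate inter-run-calibrator (IRC)
quantities divide out between-run offsets. The classic 2^-ddCq shortcut
(efficiency fixed at 2) is also provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: replicate scatter above this many Cq units is flagged for QC
REPLICATE_SD_FLAG = 0.5
#: efficiencies outside this window trigger a quality warning
EFFICIENCY_QC_RANGE = (1.8, 2.2)

REQUIRED_CQ_COLUMNS = ["plate", "well", "sample_id", "gene", "role", "dilution_log10", "cq"]


class QpcrError(ValueError):
    pass


@dataclass
class StandardCurve:
    """Least-squares standard curve of one gene: Cq = intercept + slope·log10(Q)."""

    gene: str
    slope: float
    intercept: float
    r_squared: float

    @property
    def efficiency(self) -> float:
        """Per-cycle amplification factor, 10^(-1/slope); ideal is 2."""
        return float(10.0 ** (-1.0 / self.slope))

    @property
    def valid(self) -> bool:
        return self.slope < 0

    def quality_ok(self) -> bool:
        lo, hi = EFFICIENCY_QC_RANGE
        return self.valid and lo <= self.efficiency <= hi


def fit_standard_curve(dilution_wells: pd.DataFrame, gene: str | None = None) -> StandardCurve:
    """Fit a standard curve from dilution-series wells.

    ``dilution_wells`` needs columns ``dilution_log10`` and ``cq`` (one row
    per replicate well); at least three distinct dilution levels are
    required. A non-negative slope is flagged invalid (and warned about)
    rather than raised, matching instrument-software behaviour.
    """
    d = dilution_wells["dilution_log10"].to_numpy(dtype=float)
    c = dilution_wells["cq"].to_numpy(dtype=float)
    if len(np.unique(d)) < 3:
        raise QpcrError(
            f"standard curve needs >= 3 distinct dilution levels, got {len(np.unique(d))}"
        )
    slope, intercept = np.polyfit(d, c, 1)
    resid = c - (intercept + slope * d)
    ss_tot = ((c - c.mean()) ** 2).sum()
    r2 = 1.0 - (resid**2).sum() / ss_tot if ss_tot > 0 else 1.0
    curve = StandardCurve(
        gene=gene or str(dilution_wells.get("gene", pd.Series(["?"])).iloc[0]),
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(r2),
    )
    if not curve.valid:
        warnings.warn(f"standard curve for {curve.gene} has non-negative slope", stacklevel=2)
    return curve


def relative_quantity(mean_cq: float, curve: StandardCurve, calibrator_cq: float) -> float:
    """Efficiency-corrected quantity relative to a calibrator: E^(Cq_cal − Cq)."""
    if not curve.valid:
        raise QpcrError(f"cannot quantify against invalid curve for {curve.gene}")
    return float(curve.efficiency ** (calibrator_cq - mean_cq))


def ddcq_fold(
    cq_target_sample: float,
    cq_ref_sample: float,
    cq_target_cal: float,
    cq_ref_cal: float,
) -> float:
    """Classic 2^-ddCq fold change of target vs reference, sample vs calibrator."""
    ddcq = (cq_target_sample - cq_ref_sample) - (cq_target_cal - cq_ref_cal)
    return float(2.0 ** (-ddcq))


def irc_calibrate(
    quantities_by_plate: pd.DataFrame, irc_quantities: pd.Series | dict
) -> pd.DataFrame:
    """Divide each plate's quantities by that plate's IRC quantity.

    ``quantities_by_plate`` needs columns ``plate`` and ``quantity``;
    ``irc_quantities`` maps plate id -> IRC quantity (> 0). Removes
    between-run offsets exactly when the offset is shared plate-wide.
    """
    irc = pd.Series(irc_quantities, dtype=float)
    out = quantities_by_plate.copy()
    missing = sorted(set(out["plate"]) - set(irc.index))
    if missing:
        raise QpcrError(f"missing IRC quantity for plates: {missing}")
    if (irc <= 0).any():
        raise QpcrError("IRC quantities must be > 0")
    out["calibrated_quantity"] = out["quantity"] / out["plate"].map(irc).to_numpy()
    return out


def validate_cq_table(cq: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_CQ_COLUMNS if c not in cq.columns]
    if missing:
        raise QpcrError(f"Cq table missing required columns: {missing}")
    plates_with_irc = set(cq.loc[cq["role"] == "irc", "plate"])
    all_plates = set(cq["plate"])
    if all_plates - plates_with_irc:
        raise QpcrError(
            f"plates without an inter-run calibrator: {sorted(all_plates - plates_with_irc)}"
        )


def quantify(
    cq_table: pd.DataFrame,
    efficiency_corrected: bool = True,
) -> tuple[pd.DataFrame, dict[str, StandardCurve]]:
    """Full quantification of a raw Cq table.

    Per gene: fit the standard curve from all ``standard`` wells (required
    when ``efficiency_corrected``; otherwise E is fixed at 2). Per
    (plate, gene, sample): average replicate Cq, convert to a relative
    quantity via the curve intercept (or directly from Cq when E = 2), then
    divide by the same plate's IRC quantity.

    Returns (RelQuant table, curves). The table has one row per
    (sample, gene) with mean/SD Cq, plate, raw and IRC-calibrated quantity,
    and a replicate-scatter QC flag.
    """
    validate_cq_table(cq_table)
    curves: dict[str, StandardCurve] = {}
    genes = sorted(cq_table["gene"].unique())
    for g in genes:
        std = cq_table[(cq_table["gene"] == g) & (cq_table["role"] == "standard")]
        if efficiency_corrected:
            if std.empty:
                raise QpcrError(f"no standard-dilution wells for gene {g}")
            curves[g] = fit_standard_curve(std, gene=g)
            if not curves[g].quality_ok():
                warnings.warn(
                    f"standard-curve efficiency {curves[g].efficiency:.3f} for {g} "
                    f"outside QC range {EFFICIENCY_QC_RANGE}",
                    stacklevel=2,
                )
        else:
            curves[g] = StandardCurve(
                gene=g, slope=-1.0 / np.log10(2.0), intercept=0.0, r_squared=np.nan
            )

    grouped = (
        cq_table[cq_table["role"].isin(["unknown", "irc"])]
        .groupby(["plate", "gene", "sample_id", "role"], sort=True)["cq"]
        .agg(mean_cq="mean", sd_cq="std", n_replicates="count")
        .reset_index()
    )
    # quantity relative to the gene's curve origin; any fixed reference works
    # because the IRC division below cancels it within a plate
    grouped["quantity"] = [
        float(10.0 ** ((cq - curves[g].intercept) / curves[g].slope))
        for g, cq in zip(grouped["gene"], grouped["mean_cq"])
    ]
    irc_rows = grouped[grouped["role"] == "irc"]
    out_frames = []
    for g in genes:
        sub = grouped[(grouped["gene"] == g) & (grouped["role"] == "unknown")].copy()
        irc_g = irc_rows[irc_rows["gene"] == g].set_index("plate")["quantity"]
        sub = irc_calibrate(sub, irc_g)
        out_frames.append(sub)
    rel = pd.concat(out_frames, ignore_index=True)
    rel["replicate_flag"] = rel["sd_cq"] > REPLICATE_SD_FLAG
    rel = rel.drop(columns=["role"])
    return rel, curves


def ratio_from_relquant(
    rel: pd.DataFrame, up_gene: str, down_gene: str
) -> pd.Series:
    """Per-sample calibrated-quantity ratio up_gene / down_gene."""
    wide = rel.pivot_table(
        index="sample_id", columns="gene", values="calibrated_quantity", aggfunc="mean"
    )
    for g in (up_gene, down_gene):
        if g not in wide.columns:
            raise QpcrError(f"gene {g} absent from quantification table")
    return wide[up_gene] / wide[down_gene]
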