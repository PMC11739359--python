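"""Synthetic two-timepoint septic-shock cohorts with planted ground truth.

Emulates a discovery cohort of ~100 ICU patients sampled at day 1 (D1) and
days 2-3 (D23) after admission, with ~31% ICU mortality, three recruitment
batches, planted survivor/non-survivor expression differences (some stable
across both timepoints, some timepoint-specific), outcome-linked admission
lactate, exponential survival times censored at day 30, and RT-qPCR plates
(standard dilution series, inter-run calibrator, technical replicates)
consistent with the expression matrix.

Everything is driven by one integer seed; identical configuration and seed
give bit-identical cohorts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

D1 = "D1"
D23 = "D23"
SURVIVOR = "survivor"
NONSURVIVOR = "nonsurvivor"

#: log2 range from which gene baseline means are drawn
BASELINE_LOG2_RANGE = (4.0, 12.0)
#: log2 abundance of the pooled inter-run calibrator sample, identical for
#: every assayed gene so calibrated cross-gene ratios stay interpretable
IRC_LOG2 = 8.0
#: unknown samples carried per qPCR plate (per gene panel)
PLATE_CAPACITY = 40
#: technical replicates per unknown/IRC well group
N_REPLICATES = 3
#: standard curve layout: quadruplicate wells at five ten-fold dilutions
N_STANDARD_REPLICATES = 4
STANDARD_DILUTIONS_LOG10 = (0.0, -1.0, -2.0, -3.0, -4.0)


class ConfigError(ValueError):
    """A cohort configuration violates one of its invariants."""


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters of the simulated cohort.

    Defaults reproduce the discovery-cohort geometry: 100 patients, 180
    samples (80 patients at both timepoints, 4 at day 1 only, 16 at days
    2-3 only), 31% ICU mortality, 3 batches, 39 up- and 2 down-regulated
    stable genes plus 62/134 timepoint-specific effects among 5000 genes.
    """

    n_patients: int = 100
    n_genes: int = 5000
    mortality_rate: float = 0.31
    n_both_timepoints: int = 80
    n_d1_only: int = 4
    n_d23_only: int = 16
    n_batches: int = 3
    n_up_stable: int = 39
    n_down_stable: int = 2
    n_d1_only_degs: int = 62
    n_d23_only_degs: int = 134
    effect_log2_stable: float = 1.5
    effect_log2_timepoint: float = 1.0
    within_group_sd: float = 0.7
    batch_shift_sd: float = 0.5
    batch_scale_sd: float = 0.1
    lactate_mu_survivor: float = 0.4
    lactate_sigma_survivor: float = 0.5
    lactate_mu_nonsurvivor: float = 1.0
    lactate_sigma_nonsurvivor: float = 0.5
    hazard_nonsurvivor: float = 0.12
    hazard_survivor: float = 0.004
    censor_day: float = 30.0
    qpcr_slope: float = -3.3219
    qpcr_noise_sd: float = 0.15
    qpcr_intercept_cq: float = 35.0
    plate_offset_sd: float = 0.8
    lactate_expression_coupling: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_both_timepoints + self.n_d1_only + self.n_d23_only != self.n_patients:
            raise ConfigError(
                "n_both_timepoints + n_d1_only + n_d23_only must equal n_patients "
                f"({self.n_both_timepoints}+{self.n_d1_only}+{self.n_d23_only} "
                f"!= {self.n_patients})"
            )
        n_planted = (
            self.n_up_stable
            + self.n_down_stable
            + self.n_d1_only_degs
            + self.n_d23_only_degs
        )
        if n_planted > self.n_genes:
            raise ConfigError(
                f"planted DEG counts ({n_planted}) exceed n_genes ({self.n_genes})"
            )
        if not 0.0 < self.mortality_rate < 1.0:
            raise ConfigError(f"mortality_rate must lie in (0, 1), got {self.mortality_rate}")
        for name in (
            "within_group_sd",
            "batch_shift_sd",
            "batch_scale_sd",
            "qpcr_noise_sd",
            "plate_offset_sd",
            "lactate_sigma_survivor",
            "lactate_sigma_nonsurvivor",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.hazard_nonsurvivor <= 0:
            raise ConfigError("hazard_nonsurvivor must be > 0")
        if self.hazard_survivor < 0:
            raise ConfigError("hazard_survivor must be >= 0")
        if self.n_batches < 1 or self.n_genes < 1 or self.n_patients < 1:
            raise ConfigError("n_batches, n_genes and n_patients must be >= 1")
        if self.censor_day <= 0:
            raise ConfigError("censor_day must be > 0")

    def replace(self, **changes) -> "CohortConfig":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class SampleMeta:
    """Clinical annotation of one microarray sample."""

    sample_id: str
    patient_id: str
    timepoint: str
    batch: str
    outcome: str
    lactate: float
    survival_time: float
    event: bool  # True = death observed, False = censored


@dataclass
class ExpressionCohort:
    """log2 gene x sample expression matrix plus per-sample clinical metadata.

    ``matrix`` is a DataFrame indexed by gene id with one column per sample;
    ``meta`` is indexed by sample id and aligned to the matrix columns.
    """

    matrix: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.meta.index.has_duplicates:
            raise ValueError("duplicate sample ids in metadata")
        if list(self.matrix.columns) != list(self.meta.index):
            raise ValueError("matrix columns and metadata rows must align")
        pairs = self.meta[["patient_id", "timepoint"]]
        if pairs.duplicated().any():
            raise ValueError("each (patient_id, timepoint) pair may occur at most once")
        if self.matrix.isna().any().any():
            raise ValueError("expression matrix contains missing values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def samples(self) -> list[SampleMeta]:
        return [
            SampleMeta(
                sample_id=sid,
                patient_id=row["patient_id"],
                timepoint=row["timepoint"],
                batch=row["batch"],
                outcome=row["outcome"],
                lactate=row["lactate"],
                survival_time=row["survival_time"],
                event=bool(row["event"]),
            )
            for sid, row in self.meta.iterrows()
        ]

    def subset_timepoint(self, timepoint: str) -> "ExpressionCohort":
        keep = self.meta.index[self.meta["timepoint"] == timepoint]
        return ExpressionCohort(self.matrix[keep].copy(), self.meta.loc[keep].copy())

    def patient_table(self) -> pd.DataFrame:
        """One row per patient (outcome, lactate, survival) for survival analysis."""
        cols = ["patient_id", "outcome", "lactate", "survival_time", "event"]
        return self.meta[cols].drop_duplicates("patient_id").set_index("patient_id")


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth of the planted differential-expression structure."""

    up_stable_genes: tuple[str, ...]
    down_stable_genes: tuple[str, ...]
    d1_only_genes: tuple[str, ...]
    d23_only_genes: tuple[str, ...]
    effect_log2: dict[str, float] = field(hash=False)
    hub_gene: str = ""

    def __post_init__(self) -> None:
        sets = [
            set(self.up_stable_genes),
            set(self.down_stable_genes),
            set(self.d1_only_genes),
            set(self.d23_only_genes),
        ]
        total = sum(len(s) for s in sets)
        if len(set().union(*sets)) != total:
            raise ValueError("planted gene sets must be pairwise disjoint")


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    """Independent deterministic substreams derived from one seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_cohort(config: CohortConfig) -> tuple[ExpressionCohort, PlantedTruth]:
    """Simulate an expression cohort and return it with its planted truth.

    Expression model per gene g and sample i (batch b):

        x_gi = mu_g + beta_g(outcome_i, timepoint_i) + gamma_gb + delta_gb * eps_gi

    with mu_g uniform on a plausible log2 range, eps ~ N(0, within_group_sd),
    additive batch shifts gamma ~ N(0, batch_shift_sd) and multiplicative
    noise-scale factors delta = exp(N(0, batch_scale_sd)) — the location/scale
    batch model the ComBat adjustment assumes. beta is +/- effect_log2 in
    non-survivors for planted genes at their active timepoint(s).
    """
    config.validate()
    (
        rng_genes,
        rng_assign,
        rng_expr,
        rng_batch,
        rng_lactate,
        rng_survival,
        _rng_qpcr,  # reserved so plate generation sees a stable stream
    ) = _streams(config.seed, 7)

    genes = np.array([f"G{i:05d}" for i in range(config.n_genes)])
    planted_idx = rng_genes.choice(
        config.n_genes,
        size=config.n_up_stable
        + config.n_down_stable
        + config.n_d1_only_degs
        + config.n_d23_only_degs,
        replace=False,
    )
    cuts = np.cumsum(
        [config.n_up_stable, config.n_down_stable, config.n_d1_only_degs]
    )
    up_idx, down_idx, d1_idx, d23_idx = np.split(planted_idx, cuts)

    # patients: timepoint availability is positional, outcome/batch randomized
    patients = [f"P{i:03d}" for i in range(config.n_patients)]
    avail = (
        [(True, True)] * config.n_both_timepoints
        + [(True, False)] * config.n_d1_only
        + [(False, True)] * config.n_d23_only
    )
    n_dead = int(round(config.n_patients * config.mortality_rate))
    outcome_perm = rng_assign.permutation(config.n_patients)
    dead = np.zeros(config.n_patients, dtype=bool)
    dead[outcome_perm[:n_dead]] = True
    batch_of_patient = rng_assign.integers(0, config.n_batches, size=config.n_patients)

    sample_rows = []
    for p_i, pid in enumerate(patients):
        has_d1, has_d23 = avail[p_i]
        for tp, has in ((D1, has_d1), (D23, has_d23)):
            if has:
                sample_rows.append(
                    (
                        f"{pid}_{tp}",
                        pid,
                        tp,
                        f"B{batch_of_patient[p_i] + 1}",
                        NONSURVIVOR if dead[p_i] else SURVIVOR,
                    )
                )
    meta = pd.DataFrame(
        sample_rows, columns=["sample_id", "patient_id", "timepoint", "batch", "outcome"]
    ).set_index("sample_id")

    n_samples = len(meta)
    mu = rng_expr.uniform(*BASELINE_LOG2_RANGE, size=config.n_genes)
    eps = config.within_group_sd * rng_expr.standard_normal((config.n_genes, n_samples))

    # batch effects: gene-specific additive shift, multiplicative noise scale
    gamma = config.batch_shift_sd * rng_batch.standard_normal(
        (config.n_batches, config.n_genes)
    )
    delta = np.exp(
        config.batch_scale_sd * rng_batch.standard_normal((config.n_batches, config.n_genes))
    )
    x = mu[:, None] + eps
    for b in range(config.n_batches):
        cols = (meta["batch"] == f"B{b + 1}").to_numpy()
        if cols.any():
            x[:, cols] = mu[:, None] + gamma[b][:, None] + delta[b][:, None] * eps[:, cols]

    # planted outcome effects (pure group shifts, untouched by batch scaling)
    is_dead_sample = (meta["outcome"] == NONSURVIVOR).to_numpy()
    is_d1 = (meta["timepoint"] == D1).to_numpy()
    is_d23 = ~is_d1
    tp_signs_d1 = np.where(np.arange(len(d1_idx)) % 2 == 0, 1.0, -1.0)
    tp_signs_d23 = np.where(np.arange(len(d23_idx)) % 2 == 0, 1.0, -1.0)
    x[np.ix_(up_idx, is_dead_sample)] += config.effect_log2_stable
    x[np.ix_(down_idx, is_dead_sample)] -= config.effect_log2_stable
    x[np.ix_(d1_idx, is_dead_sample & is_d1)] += (
        config.effect_log2_timepoint * tp_signs_d1[:, None]
    )
    x[np.ix_(d23_idx, is_dead_sample & is_d23)] += (
        config.effect_log2_timepoint * tp_signs_d23[:, None]
    )

    # clinical covariates at patient level
    lact_mu = np.where(dead, config.lactate_mu_nonsurvivor, config.lactate_mu_survivor)
    lact_sd = np.where(
        dead, config.lactate_sigma_nonsurvivor, config.lactate_sigma_survivor
    )
    lact_noise = rng_lactate.standard_normal(config.n_patients)
    lactate = np.exp(lact_mu + lact_sd * lact_noise)
    if config.lactate_expression_coupling != 0.0:
        # optional stress-test coupling: shift lactate with the patient's mean
        # planted-up expression (z-scored), keeping marginals roughly lognormal
        up_gene_mean = np.full(config.n_patients, np.nan)
        mat = pd.DataFrame(x, index=genes, columns=meta.index)
        per_sample = mat.iloc[up_idx].mean(axis=0)
        for p_i, pid in enumerate(patients):
            own = meta.index[meta["patient_id"] == pid]
            up_gene_mean[p_i] = per_sample[own].mean()
        z = (up_gene_mean - up_gene_mean.mean()) / up_gene_mean.std()
        lactate = np.exp(
            lact_mu + lact_sd * lact_noise + config.lactate_expression_coupling * z
        )

    outcomes = pd.Series(
        np.where(dead, NONSURVIVOR, SURVIVOR), index=patients, name="outcome"
    )
    surv = generate_survival(outcomes, config, rng=rng_survival)

    meta["lactate"] = meta["patient_id"].map(dict(zip(patients, lactate)))
    meta["survival_time"] = meta["patient_id"].map(surv["survival_time"])
    meta["event"] = meta["patient_id"].map(surv["event"]).astype(bool)

    cohort = ExpressionCohort(pd.DataFrame(x, index=genes, columns=meta.index), meta)

    effect_map: dict[str, float] = {}
    for idx_arr, eff in (
        (up_idx, config.effect_log2_stable),
        (down_idx, -config.effect_log2_stable),
    ):
        for g in genes[idx_arr]:
            effect_map[g] = eff
    for idx_arr, signs in ((d1_idx, tp_signs_d1), (d23_idx, tp_signs_d23)):
        for g, s in zip(genes[idx_arr], signs):
            effect_map[g] = s * config.effect_log2_timepoint

    truth = PlantedTruth(
        up_stable_genes=tuple(genes[up_idx]),
        down_stable_genes=tuple(genes[down_idx]),
        d1_only_genes=tuple(genes[d1_idx]),
        d23_only_genes=tuple(genes[d23_idx]),
        effect_log2=effect_map,
        hub_gene=str(genes[up_idx][0]) if len(up_idx) else "",
    )
    return cohort, truth


def generate_survival(
    outcomes: pd.Series,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Exponential ICU survival times per patient, censored at ``censor_day``.

    Non-survivors (ICU deaths by definition) have their event time rejection-
    sampled until it falls within the censoring window, so every non-survivor
    records an observed death. Survivor times beyond the window are censored
    at ``censor_day``.
    """
    if config.hazard_nonsurvivor <= 0:
        raise ConfigError("hazard_nonsurvivor must be > 0")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    times = np.empty(len(outcomes))
    events = np.empty(len(outcomes), dtype=bool)
    for i, outcome in enumerate(outcomes):
        if outcome == NONSURVIVOR:
            t = rng.exponential(1.0 / config.hazard_nonsurvivor)
            while t > config.censor_day:
                t = rng.exponential(1.0 / config.hazard_nonsurvivor)
            times[i], events[i] = t, True
        else:
            if config.hazard_survivor == 0:
                times[i], events[i] = config.censor_day, False
            else:
                t = rng.exponential(1.0 / config.hazard_survivor)
                if t > config.censor_day:
                    times[i], events[i] = config.censor_day, False
                else:
                    # discharge-alive events are censored observations
                    times[i], events[i] = t, False
    return pd.DataFrame(
        {"survival_time": times, "event": events}, index=outcomes.index
    )


def generate_qpcr_plates(
    cohort: ExpressionCohort,
    target_genes: list[str],
    config: CohortConfig,
    samples: list[str] | None = None,
) -> pd.DataFrame:
    """Simulate raw RT-qPCR Cq tables for ``target_genes``.

    Returns a long-format table with columns
    ``plate, well, sample_id, gene, role, dilution_log10, cq`` where role is
    ``unknown`` / ``standard`` / ``irc``. The generating model is

        Cq = intercept_g + slope * log10(relative copies) + run_offset_p + noise

    with relative copies = 2^(log2 expression). Each plate carries its own
    run offset shared by all wells, a replicated inter-run calibrator (a
    pooled sample with identical log2 abundance for every gene), and the
    first plate additionally carries quadruplicate ten-fold standard-dilution
    series per gene, so downstream IRC calibration can remove the offsets
    exactly in expectation.
    """
    missing = [g for g in target_genes if g not in cohort.matrix.index]
    if missing:
        raise KeyError(f"target genes not in cohort: {missing}")
    if samples is None:
        samples = list(cohort.matrix.columns)
    rng = _streams(config.seed, 7)[6]

    slope = config.qpcr_slope
    log10_2 = np.log10(2.0)
    intercepts = {
        g: config.qpcr_intercept_cq + i * 0.5 for i, g in enumerate(target_genes)
    }

    chunks = [
        samples[i : i + PLATE_CAPACITY] for i in range(0, len(samples), PLATE_CAPACITY)
    ]
    offsets = config.plate_offset_sd * rng.standard_normal(len(chunks))

    rows = []
    for p_i, chunk in enumerate(chunks):
        plate = f"plate{p_i + 1}"
        well = 0
        if p_i == 0:
            for g in target_genes:
                for d in STANDARD_DILUTIONS_LOG10:
                    for _ in range(N_STANDARD_REPLICATES):
                        well += 1
                        cq = (
                            intercepts[g]
                            + slope * d
                            + offsets[p_i]
                            + config.qpcr_noise_sd * rng.standard_normal()
                        )
                        rows.append(
                            (plate, f"W{well:03d}", "STD", g, "standard", d, cq)
                        )
        for g in target_genes:
            for _ in range(N_REPLICATES):
                well += 1
                q_log10 = IRC_LOG2 * log10_2
                cq = (
                    intercepts[g]
                    + slope * q_log10
                    + offsets[p_i]
                    + config.qpcr_noise_sd * rng.standard_normal()
                )
                rows.append((plate, f"W{well:03d}", "IRC", g, "irc", np.nan, cq))
        for sid in chunk:
            for g in target_genes:
                log2_expr = float(cohort.matrix.at[g, sid])
                q_log10 = log2_expr * log10_2
                for _ in range(N_REPLICATES):
                    well += 1
                    cq = (
                        intercepts[g]
                        + slope * q_log10
                        + offsets[p_i]
                        + config.qpcr_noise_sd * rng.standard_normal()
                    )
                    rows.append((plate, f"W{well:03d}", sid, g, "unknown", np.nan, cq))

    return pd.DataFrame(
        rows,
        columns=["plate", "well", "sample_id", "gene", "role", "dilution_log10", "cq"],
    )


def generate_networks(
    truth: PlantedTruth,
    config: CohortConfig,
    n_networks: int = 3,
    background_edges: int = 300,
) -> list[pd.DataFrame]:
    """Synthetic interaction networks wired so ``truth.hub_gene`` is the hub.

    Each network contains a star centred on the designated hub gene covering
    most other up-stable genes, a sparse ring among the remaining up genes,
    and random background edges among non-planted genes. Returned as edge-list
    DataFrames (gene_a, gene_b, weight) ready to be written as TSV.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(8)[7])
    up = list(truth.up_stable_genes)
    hub = truth.hub_gene or (up[0] if up else "HUB")
    others = [g for g in up if g != hub]
    all_genes = [f"G{i:05d}" for i in range(config.n_genes)]
    nets = []
    for k in range(n_networks):
        edges: list[tuple[str, str, float]] = []
        # star on the hub, dropping a few spokes per network for realism
        n_drop = min(k, max(0, len(others) - 3))
        spokes = others[n_drop:] if n_drop else others
        for g in spokes:
            edges.append((hub, g, 1.0))
        # weak chain among non-hub up genes (keeps their degree ~2 << hub)
        for a, b in zip(others, others[1:]):
            edges.append((a, b, 1.0))
        for _ in range(background_edges):
            a, b = rng.choice(len(all_genes), size=2, replace=False)
            edges.append((all_genes[a], all_genes[b], 1.0))
        nets.append(pd.DataFrame(edges, columns=["gene_a", "gene_b", "weight"]))
    return nets
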