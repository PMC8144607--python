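"""Synthetic cohorts with known ground truth for the full pipeline.

The generator emulates the statistical structure the analysis assumes: a
cohort of patients split into recurrent (DFS < 1 year) and non-recurrent
groups; duplicate per-patient peak calls drawn from a shared disjoint atlas
template with boundary jitter and replicate-private noise peaks; peak x
sample counts that are negative-binomial with planted differential peaks and
nuisance covariates; a binary motif matrix with TFs enriched in differential
peaks; two-channel array scans whose class medians shift with prognosis
group; and exponential survival times with a group hazard ratio and
independent censoring.

Every draw derives from the single seed in :class:`SimulationConfig`, so a
fixed configuration reproduces the cohort byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .atlas import PeakAtlas, PeakInterval, PeakSet

LN2 = np.log(2.0)


class ConfigError(ValueError):
    """Invalid simulation configuration."""


# default linear-scale class medians per (prognosis group, probe class);
# chosen so cohort blue scores center on ~0.6 with CTRL - CGH = 4
DEFAULT_CLASS_MEDIANS = {
    ("good", "GREEN"): 5.0,
    ("good", "BLACK"): 1.0,
    ("good", "BLUE"): 2.88,  # blue_score 0.72
    ("good", "RED"): 1.40,
    ("poor", "GREEN"): 5.0,
    ("poor", "BLACK"): 1.0,
    ("poor", "BLUE"): 1.92,  # blue_score 0.48
    ("poor", "RED"): 2.40,
}


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic cohort.

    Defaults mirror a discovery-scale cohort: 16 patients of which 6 are
    recurrent, ~100 expected fragments per peak, NB dispersion 0.05
    (Var = mu + alpha mu^2), planted |log2FC| = 2 differential peaks and a
    group hazard ratio of 3 on exponential DFS with a non-recurrent median
    of 845 days.
    """

    n_patients: int = 16
    frac_recurrent: float = 0.375
    n_atlas_peaks: int = 1000
    n_diff_open_recurrent: int = 50
    n_diff_open_nonrecurrent: int = 75
    base_mean: float = 100.0
    dispersion: float = 0.05
    planted_lfc: float = 2.0
    n_tfs: int = 20
    motif_density: float = 0.1
    planted_tf_effects: dict = field(
        default_factory=lambda: {"TF_01": 1.0, "TF_02": -1.0}
    )
    array_noise_sd: float = 0.1
    hazard_ratio_groups: float = 3.0
    censor_rate: float = 0.2
    seed: int = 0
    # geometry / nuisance structure
    chrom: str = "chrS"
    peak_length: int = 500
    peak_gap: int = 500
    peak_presence: float = 0.9
    boundary_jitter_sd: float = 10.0
    noise_peak_frac: float = 0.1
    noise_peak_length: int = 200
    median_dfs_nonrecurrent: float = 845.0
    covariate_depth_coef: float = 0.3
    covariate_margin_coef: float = 0.2
    motif_enrichment_scale: float = 0.4
    class_medians: dict = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MEDIANS)
    )

    def validate(self) -> "SimulationConfig":
        for name in ("frac_recurrent", "motif_density", "censor_rate",
                     "peak_presence", "noise_peak_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name}={v} must lie in [0, 1]")
        if not 0 < self.frac_recurrent < 1:
            raise ConfigError("frac_recurrent must lie strictly in (0, 1)")
        if self.n_diff_open_recurrent + self.n_diff_open_nonrecurrent >= \
                self.n_atlas_peaks:
            raise ConfigError("planted differential peaks must be fewer than "
                              "atlas peaks")
        if self.base_mean <= 0 or self.dispersion < 0:
            raise ConfigError("base_mean must be > 0 and dispersion >= 0")
        if self.array_noise_sd <= 0:
            raise ConfigError("array_noise_sd must be positive")
        if self.hazard_ratio_groups <= 0:
            raise ConfigError("hazard_ratio_groups must be positive")
        return self

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass
class CohortTruth:
    """Ground truth of a simulated cohort."""

    clinical: pd.DataFrame  # patient, group, dfs_days, event, covariates
    template: list[PeakInterval]  # disjoint atlas template
    diff_peaks: pd.Series  # template peak id -> +1 (open in recurrent) / -1
    tf_effects: dict
    hazard_rates: dict  # group -> exponential rate (per day)

    @property
    def patients(self) -> list[str]:
        return self.clinical.index.tolist()

    def group_of(self, patient: str) -> str:
        return self.clinical.loc[patient, "group"]


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(config.seed) % (2**31), stream])
    )


def _make_template(config: SimulationConfig) -> list[PeakInterval]:
    step = config.peak_length + config.peak_gap
    return [
        PeakInterval(config.chrom, 1000 + i * step,
                     1000 + i * step + config.peak_length)
        for i in range(config.n_atlas_peaks)
    ]


def simulate_cohort(config: SimulationConfig) -> CohortTruth:
    """Draw the cohort: groups, survival, covariates and planted truth.

    Group sizes are ``round(n_patients * frac_recurrent)`` recurrent and the
    complement non-recurrent.  DFS is exponential with the non-recurrent
    median at ``median_dfs_nonrecurrent`` days and the recurrent rate scaled
    by ``hazard_ratio_groups``; censoring is Bernoulli(``censor_rate``) with
    the censoring time uniform before the event.  Covariates: nuclear read
    depth log-normal, margin status Bernoulli(0.3).
    """
    config.validate()
    rng = _rng(config, 0)
    n_rec = int(round(config.n_patients * config.frac_recurrent))
    n_non = config.n_patients - n_rec
    patients = [f"PT{i + 1:03d}" for i in range(config.n_patients)]
    groups = np.array(["recurrent"] * n_rec + ["non_recurrent"] * n_non)

    rate_non = LN2 / config.median_dfs_nonrecurrent
    rate_rec = rate_non * config.hazard_ratio_groups
    rates = np.where(groups == "recurrent", rate_rec, rate_non)
    t_event = rng.exponential(1.0 / rates)
    censored = rng.random(config.n_patients) < config.censor_rate
    u = rng.random(config.n_patients)
    dfs = np.where(censored, t_event * u, t_event)
    dfs = np.maximum(np.round(dfs, 1), 1.0)

    depth = rng.lognormal(mean=np.log(4e7), sigma=0.4, size=config.n_patients)
    margin = (rng.random(config.n_patients) < 0.3).astype(int)

    clinical = pd.DataFrame(
        {
            "group": groups,
            "dfs_days": dfs,
            "event": (~censored).astype(int),
            "nuclear_read_depth": depth,
            "margin_status": margin,
        },
        index=pd.Index(patients, name="patient"),
    )

    template = _make_template(config)
    ids = [iv.peak_id for iv in template]
    pick = rng.choice(
        config.n_atlas_peaks,
        size=config.n_diff_open_recurrent + config.n_diff_open_nonrecurrent,
        replace=False,
    )
    diff = pd.Series(0, index=ids, dtype=int)
    diff.iloc[pick[: config.n_diff_open_recurrent]] = 1
    diff.iloc[pick[config.n_diff_open_recurrent:]] = -1
    diff = diff[diff != 0]

    return CohortTruth(
        clinical=clinical,
        template=template,
        diff_peaks=diff,
        tf_effects=dict(config.planted_tf_effects),
        hazard_rates={"recurrent": rate_rec, "non_recurrent": rate_non},
    )


def simulate_peak_sets(
    truth: CohortTruth, config: SimulationConfig
) -> dict[str, tuple[PeakSet, PeakSet]]:
    """Duplicate per-patient peak calls from the shared atlas template.

    Each patient carries a Bernoulli(``peak_presence``) subset of template
    peaks, present in both replicates with independent Gaussian boundary
    jitter, plus replicate-private noise peaks placed in the gaps between
    template peaks.
    """
    config.validate()
    rng = _rng(config, 1)
    out = {}
    template = truth.template
    for patient in truth.patients:
        present = rng.random(len(template)) < config.peak_presence
        reps = []
        for _rep in (1, 2):
            ivs = []
            for iv, keep in zip(template, present):
                if not keep:
                    continue
                js, je = 0, 0
                if config.boundary_jitter_sd > 0:
                    js = int(round(rng.normal(0, config.boundary_jitter_sd)))
                    je = int(round(rng.normal(0, config.boundary_jitter_sd)))
                start = max(0, iv.start + js)
                end = max(start + 1, iv.end + je)
                ivs.append(PeakInterval(iv.chrom, start, end))
            n_noise = int(round(config.noise_peak_frac * present.sum()))
            for _ in range(n_noise):
                slot = int(rng.integers(0, len(template)))
                gap_start = template[slot].end + 50
                gap_end = gap_start + config.peak_gap - 100
                if gap_end - gap_start <= config.noise_peak_length:
                    continue
                s = int(rng.integers(gap_start,
                                     gap_end - config.noise_peak_length))
                ivs.append(
                    PeakInterval(config.chrom, s, s + config.noise_peak_length)
                )
            reps.append(PeakSet(patient, ivs))
        out[patient] = (reps[0], reps[1])
    return out


def _match_planted(atlas: PeakAtlas, truth: CohortTruth) -> pd.Series:
    """Map atlas peaks to planted directions by best template overlap."""
    diff_ivs = []
    for pid, direction in truth.diff_peaks.items():
        chrom, rng_ = pid.split(":")
        s, e = (int(x) for x in rng_.split("-"))
        diff_ivs.append((PeakInterval(chrom, s, e), direction))
    directions = pd.Series(0, index=atlas.peak_ids, dtype=int)
    for iv in atlas.intervals:
        best, best_ov = 0, 0
        for tiv, direction in diff_ivs:
            ov = iv.intersection_length(tiv)
            if ov > best_ov:
                best_ov, best = ov, direction
        if best_ov > 0.5 * iv.length:
            directions[iv.peak_id] = best
    return directions


def simulate_counts_and_motifs(
    truth: CohortTruth, atlas: PeakAtlas, config: SimulationConfig
):
    """NB counts over the atlas plus the binary motif matrix.

    Counts are NB with mean ``base_mean * sf_s * 2^(lfc_p * group_s +
    covariate effects)`` and dispersion ``config.dispersion``; atlas peaks
    matching a planted template peak get log2FC ``±planted_lfc``.  The motif
    matrix is Bernoulli(``motif_density``) background with each planted TF's
    hit probability raised in the differential peaks whose direction matches
    the sign of its effect, so ridge coefficients recover the effect signs.

    Returns ``(counts, metadata, motif_hits, directions)`` where
    ``directions`` maps each atlas peak to +1/-1/0 planted direction.
    """
    config.validate()
    if len(atlas) == 0:
        raise ValueError("atlas is empty")
    if atlas.intervals[0].chrom != config.chrom:
        raise ValueError("atlas/config mismatch: different chromosome")
    rng = _rng(config, 2)
    directions = _match_planted(atlas, truth)
    lfc = directions.to_numpy(float) * config.planted_lfc

    clin = truth.clinical
    group = (clin["group"] == "recurrent").to_numpy(float)
    zdepth = np.log(clin["nuclear_read_depth"].to_numpy(float))
    zdepth = (zdepth - zdepth.mean()) / max(zdepth.std(), 1e-12)
    margin = clin["margin_status"].to_numpy(float)
    sf = rng.lognormal(0.0, 0.2, size=len(clin))

    log2_mu = (
        np.log2(config.base_mean)
        + np.outer(lfc, group)
        + config.covariate_depth_coef * zdepth
        + config.covariate_margin_coef * margin
    )
    mu = np.power(2.0, log2_mu) * sf
    if config.dispersion > 0:
        r = 1.0 / config.dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    else:
        counts = rng.poisson(mu)
    counts_df = pd.DataFrame(counts, index=atlas.peak_ids,
                             columns=truth.patients)

    metadata = clin[["group", "nuclear_read_depth", "margin_status"]].copy()

    tf_names = [f"TF_{i + 1:02d}" for i in range(config.n_tfs)]
    for tf in config.planted_tf_effects:
        if tf not in tf_names:
            raise ConfigError(f"planted TF {tf!r} outside the {config.n_tfs} "
                              "simulated TFs")
    hits = (rng.random((len(atlas), config.n_tfs))
            < config.motif_density).astype(np.int8)
    dvec = directions.to_numpy()
    for j, tf in enumerate(tf_names):
        effect = config.planted_tf_effects.get(tf)
        if not effect:
            continue
        target = 1 if effect > 0 else -1
        sel = dvec == target
        p = min(0.95, config.motif_density
                + abs(effect) * config.motif_enrichment_scale)
        hits[sel, j] = (rng.random(sel.sum()) < p).astype(np.int8)
    motif_hits = pd.DataFrame(hits, index=atlas.peak_ids, columns=tf_names)
    return counts_df, metadata, motif_hits, directions


def simulate_array_scans(
    truth: CohortTruth, probes: pd.DataFrame, config: SimulationConfig
) -> dict[str, pd.DataFrame]:
    """Two-channel scans whose class medians track the prognosis group.

    Per probe, the log2 Cy5/Cy3 ratio is Normal(log2 class median,
    ``array_noise_sd``), so the linear-scale class median equals the
    configured target; Cy3 reference intensities are log-normal and strictly
    positive.  Recurrent patients draw from the ``poor`` medians,
    non-recurrent from ``good``.
    """
    config.validate()
    rng = _rng(config, 3)
    klass = probes["klass"].to_numpy()
    out = {}
    for patient in truth.patients:
        prognosis = ("poor" if truth.group_of(patient) == "recurrent"
                     else "good")
        log2_med = np.array([
            np.log2(config.class_medians[(prognosis, c)]) for c in klass
        ])
        log_ratio = rng.normal(log2_med, config.array_noise_sd)
        cy3 = rng.lognormal(np.log(500.0), 0.3, size=len(klass))
        cy5 = np.power(2.0, log_ratio) * cy3
        out[patient] = pd.DataFrame(
            {"probe_id": probes["probe_id"].to_numpy(),
             "cy5": cy5, "cy3": cy3}
        )
    return out


def default_probe_set(
    config: SimulationConfig,
    n_red_regions: int = 244,
    n_blue_regions: int = 688,
    n_green_regions: int = 312,
    n_black_probes: int = 7000,
    probes_per_region: int = 5,
) -> pd.DataFrame:
    """Probe table mirroring the array design's class structure.

    RED and BLUE regions tile signature regions; GREEN are positive-control
    regions open in all tumors; BLACK are backbone single probes.  Region
    counts default to the arrayed design (244 RED + 688 BLUE = 932 signature
    regions, 312 GREEN, ~7000 BLACK probes).
    """
    from .array import design_probes

    rows = []
    pos = 10_000_000  # away from the count-simulation template
    for klass, n in (("RED", n_red_regions), ("BLUE", n_blue_regions),
                     ("GREEN", n_green_regions)):
        for i in range(n):
            rows.append((f"{klass}_{i:04d}", config.chrom, pos, pos + 400,
                         klass))
            pos += 1000
    regions = pd.DataFrame(
        rows, columns=["region_id", "chrom", "start", "end", "klass"]
    )
    probes = design_probes(regions, probes_per_region=probes_per_region)
    black = pd.DataFrame(
        {
            "probe_id": [f"BLACK_{i:05d}" for i in range(n_black_probes)],
            "chrom": config.chrom,
            "start": [pos + i * 1000 for i in range(n_black_probes)],
            "end": [pos + i * 1000 + 60 for i in range(n_black_probes)],
            "klass": "BLACK",
            "region_id": [f"BLACKR_{i:05d}" for i in range(n_black_probes)],
        }
    )
    return pd.concat([probes, black], ignore_index=True)


def simulate_expression_lfc(
    truth: CohortTruth,
    config: SimulationConfig,
    shift_closed: float = -1.0,
    shift_open: float = 0.0,
    background_sd: float = 0.5,
):
    """Expression log2 fold changes for genes nearest the template peaks.

    One gene per template peak, TSS at the peak midpoint.  Genes nearest
    differentially closed peaks (open in non-recurrent) get their expression
    log2FC shifted by ``shift_closed`` (downregulated in recurrent tumors by
    default); genes near differentially open peaks by ``shift_open``.
    Returns ``(expression_lfc, gene_annotations)``.
    """
    rng = _rng(config, 4)
    genes, chroms, tss, lfcs = [], [], [], []
    for i, iv in enumerate(truth.template):
        gene = f"G{i + 1:05d}"
        genes.append(gene)
        chroms.append(iv.chrom)
        tss.append((iv.start + iv.end) // 2)
        d = truth.diff_peaks.get(iv.peak_id, 0)
        shift = shift_closed if d == -1 else (shift_open if d == 1 else 0.0)
        lfcs.append(rng.normal(shift, background_sd))
    annotations = pd.DataFrame({"gene": genes, "chrom": chroms, "tss": tss})
    return pd.Series(lfcs, index=genes, name="log2fc"), annotations
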