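"""Synthetic cohorts with the statistical structure the pipeline assumes.

Three generators cover the pipeline's inputs end to end, so every stage is
testable without any external download:

* :func:`generate_expression_cohort` draws a two-group (durable responder
  vs non-responder) bulk RNA-seq counts matrix from a negative-binomial
  model with per-gene dispersion, log-normal library sizes and base means,
  a designated CAF-marker subset carrying planted up-regulation in
  responders, and designated G2M/E2F subsets carrying planted
  down-regulation.  The planted truth is returned for recovery tests.
* :func:`simulate_growth_and_label` draws piecewise-exponential tumor-volume
  trajectories, labels them durable response (DR), short-lived response
  (SR) or non-responder (NR) by documented rules, and derives survival
  records from the 1500 mm^3 humane-endpoint rule.
* toy proteins + missense mutations for the neo-antigen stage.

All randomness flows from a single seed through spawned child streams, so
each component is independently reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort_io import ExpressionMatrix, write_expression_matrix, write_gmt

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "GrowthConfig",
    "generate_expression_cohort",
    "tumor_volume",
    "simulate_growth_and_label",
    "generate_toy_proteome",
    "write_cohort",
]

#: humane endpoint: animals are euthanized at this cumulative tumor burden
ENDPOINT_MM3 = 1500.0


@dataclass
class SimulationConfig:
    """Parameters of the expression-cohort simulation.

    Defaults emulate the mouse discovery cohort: 6 durable responders vs 8
    non-responders, ~2,000 expressed genes, 50 CAF markers of which 10 carry
    a planted +1.5 log2 effect in responders, 120 cell-cycle genes of which
    7 carry a planted -1.5 log2 effect, per-gene NB dispersion 0.2,
    log-normal library-size spread (sigma = 0.25) and log-normal base means
    (meanlog 4, sdlog 1.5) typical of bulk RNA-seq.
    """

    n_genes: int = 2000
    n_dr: int = 6
    n_nr: int = 8
    n_caf_markers: int = 50
    n_planted_stroma: int = 10
    delta_up: float = 1.5  # log2 effect in DR for planted stroma genes
    n_cellcycle_genes: int = 120
    n_planted_prolif: int = 7
    delta_down: float = 1.5  # log2 effect magnitude, downward in DR
    base_mean_log: float = 4.0  # meanlog of the log-normal base-mean draw
    base_mean_sdlog: float = 1.5
    dispersion: float = 0.2
    library_sdlog: float = 0.25
    gene_length_range: tuple[int, int] = (500, 10000)
    paired_timepoints: bool = False
    pair_effect_sdlog: float = 0.1  # shared within-pair log-mean random effect
    seed: int = 0

    def validate(self) -> None:
        if self.n_planted_stroma > self.n_caf_markers:
            raise ValueError("planted stroma genes exceed CAF marker count")
        if self.n_planted_prolif > self.n_cellcycle_genes:
            raise ValueError("planted proliferation genes exceed cell-cycle count")
        if self.n_caf_markers + self.n_cellcycle_genes > self.n_genes:
            raise ValueError("marker sets exceed gene universe")
        for name in (
            "n_genes",
            "n_dr",
            "n_nr",
            "dispersion",
            "base_mean_sdlog",
            "library_sdlog",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SimulationTruth:
    """Ground truth of one simulated cohort: what recovery tests check."""

    planted_stroma: list[str]
    planted_prolif: list[str]
    delta_up: float
    delta_down: float
    base_means: dict[str, float]
    dispersion: float
    seed: int


def generate_expression_cohort(
    config: SimulationConfig, counts_seed: int | None = None
) -> dict:
    """Simulate a two-group NB counts cohort with planted signature effects.

    Counts are drawn as NB(mean = q_g * sf_s * 2^(effect_g * I[s is DR]),
    dispersion alpha), where q_g is the gene's base mean, sf_s a log-normal
    library-size factor, and effect_g is +delta_up for planted stroma genes,
    -delta_down for planted proliferation genes, 0 otherwise.  With
    ``paired_timepoints`` each subject contributes a pre-treatment sample
    (no planted effect) and an on-treatment sample, sharing a within-pair
    random effect on the log mean.

    The cohort *structure* (marker-set assignment, planted genes, base
    means, gene lengths) is determined by ``config.seed``; the count
    *sampling* stream defaults to the same seed but can be redirected with
    ``counts_seed`` to draw an independent cohort from the same underlying
    biology (e.g. a held-out validation cohort).

    Returns a dict with keys ``counts`` (ExpressionMatrix),
    ``gene_lengths`` (Series), ``samples`` (DataFrame), ``gene_sets``
    (dict name -> gene list) and ``truth`` (SimulationTruth).
    """
    config.validate()
    rng_genes = np.random.default_rng(
        np.random.SeedSequence(config.seed).spawn(3)[0]
    )
    sampling = np.random.SeedSequence(
        config.seed if counts_seed is None else counts_seed
    ).spawn(3)
    rng_counts = np.random.default_rng(sampling[1])
    rng_lib = np.random.default_rng(sampling[2])

    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    perm = rng_genes.permutation(config.n_genes)
    caf_idx = perm[: config.n_caf_markers]
    cc_idx = perm[
        config.n_caf_markers : config.n_caf_markers + config.n_cellcycle_genes
    ]
    caf_markers = [genes[i] for i in np.sort(caf_idx)]
    cellcycle = [genes[i] for i in np.sort(cc_idx)]
    planted_stroma = sorted(
        rng_genes.choice(caf_markers, config.n_planted_stroma, replace=False)
    )
    planted_prolif = sorted(
        rng_genes.choice(cellcycle, config.n_planted_prolif, replace=False)
    )
    # split the cell-cycle genes into overlapping G2M/E2F stand-in sets
    n_cc = len(cellcycle)
    cut = int(math.ceil(n_cc * 0.6))
    g2m = cellcycle[:cut]
    e2f = cellcycle[n_cc - cut :]

    base_means = rng_genes.lognormal(
        config.base_mean_log, config.base_mean_sdlog, config.n_genes
    )
    lengths = rng_genes.integers(
        config.gene_length_range[0], config.gene_length_range[1] + 1, config.n_genes
    )

    effect = np.zeros(config.n_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for g in planted_stroma:
        effect[gene_pos[g]] = config.delta_up
    for g in planted_prolif:
        effect[gene_pos[g]] = -config.delta_down

    subjects = [f"DR{i + 1}" for i in range(config.n_dr)] + [
        f"NR{i + 1}" for i in range(config.n_nr)
    ]
    is_dr = np.array([s.startswith("DR") for s in subjects])

    rows = []
    sample_ids: list[str] = []
    col_specs: list[tuple[int, bool, float]] = []  # (subject index, on-treatment, pair effect)
    timepoints = ("pre", "on") if config.paired_timepoints else ("on",)
    pair_fx = (
        rng_lib.normal(0.0, config.pair_effect_sdlog, len(subjects))
        if config.paired_timepoints
        else np.zeros(len(subjects))
    )
    for j, subj in enumerate(subjects):
        for tp in timepoints:
            sid = f"{subj}_{tp}" if config.paired_timepoints else subj
            sample_ids.append(sid)
            col_specs.append((j, tp == "on", pair_fx[j]))
            rows.append(
                {
                    "sample_id": sid,
                    "response_label": "DR" if is_dr[j] else "NR",
                    "timepoint": tp,
                    "pair_id": subj if config.paired_timepoints else "",
                    "cohort": "synthetic",
                }
            )
    samples = pd.DataFrame(rows)

    n_samples = len(sample_ids)
    lib_factors = rng_lib.lognormal(0.0, config.library_sdlog, n_samples)
    counts = np.empty((config.n_genes, n_samples), dtype=np.int64)
    alpha = config.dispersion
    for s, (j, on, pfx) in enumerate(col_specs):
        fold = np.exp2(effect) if (is_dr[j] and on) else 1.0
        mu = base_means * lib_factors[s] * math.exp(pfx) * fold
        if alpha > 0:
            n_param = 1.0 / alpha
            p_param = n_param / (n_param + mu)
            counts[:, s] = rng_counts.negative_binomial(n_param, p_param)
        else:
            counts[:, s] = rng_counts.poisson(mu)

    matrix = ExpressionMatrix(
        pd.DataFrame(counts, index=genes, columns=sample_ids), "counts"
    )
    truth = SimulationTruth(
        planted_stroma=list(planted_stroma),
        planted_prolif=list(planted_prolif),
        delta_up=config.delta_up,
        delta_down=config.delta_down,
        base_means=dict(zip(genes, base_means)),
        dispersion=config.dispersion,
        seed=config.seed,
    )
    return {
        "counts": matrix,
        "gene_lengths": pd.Series(lengths, index=genes, name="length_bp"),
        "samples": samples,
        "gene_sets": {
            "CAF_MARKERS": caf_markers,
            "G2M_CHECKPOINT": g2m,
            "E2F_TARGETS": e2f,
        },
        "truth": truth,
    }


def tumor_volume(length_mm: float, width_mm: float, depth_mm: float) -> float:
    """Caliper tumor volume in mm^3: L * W * D * pi / 6."""
    if length_mm < 0 or width_mm < 0 or depth_mm < 0:
        raise ValueError("dimensions must be non-negative")
    return length_mm * width_mm * depth_mm * math.pi / 6.0


@dataclass
class GrowthConfig:
    """Parameters of the tumor-growth / survival simulation.

    Response-category mixture for the treated arm follows the observed
    tumor counts (13 DR, 6 SR, 34 NR of 53).
    """

    n_treated: int = 53
    n_control: int = 19
    study_days: int = 90
    measure_every: int = 3
    baseline_mm3: float = 100.0
    p_dr: float = 13 / 53
    p_sr: float = 6 / 53
    growth_rate: float = 0.08  # per-day exponential rate, untreated growth
    shrink_rate: float = 0.10
    relapse_rate: float = 0.09
    response_onset_day: float = 6.0
    noise_sdlog: float = 0.03  # multiplicative measurement noise on volume


def _classify_trajectory(days: np.ndarray, volumes: np.ndarray) -> str:
    """DR/SR/NR from a realized volume trajectory.

    DR: volume never exceeds 1.2x baseline after day 14 and ends at or
    below baseline.  SR: shrinks >= 30% below baseline at some point, then
    exceeds baseline before study end.  NR: otherwise.
    """
    baseline = volumes[0]
    after14 = volumes[days > 14]
    if after14.size and (after14 <= 1.2 * baseline).all() and volumes[-1] <= baseline:
        return "DR"
    shrunk = np.where(volumes <= 0.7 * baseline)[0]
    if shrunk.size and (volumes[shrunk[0] :] > baseline).any():
        return "SR"
    return "NR"


def simulate_growth_and_label(
    config: GrowthConfig | None = None, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate tumor-growth trajectories and derive survival records.

    Each tumor grows piecewise-exponentially: untreated tumors (and treated
    non-responders) grow at ``growth_rate``; responders shrink at
    ``shrink_rate`` from ``response_onset_day``; short-lived responders
    additionally relapse at ``relapse_rate`` from a random day in the
    second half of the shrink phase.  Volumes carry log-normal measurement
    noise, and L = W = D dimensions are back-computed from the volume.

    Returns ``(growth, survival)``: per-measurement records (tumor_id, day,
    L/W/D mm, volume mm^3, arm, response_category) and per-animal survival
    records (subject_id, time, event, group), with the event at the first
    day the trajectory reaches 1500 mm^3 and censoring at study end.
    """
    config = config or GrowthConfig()
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    days = np.arange(0, config.study_days + 1, config.measure_every)

    growth_rows = []
    survival_rows = []
    arms = ["anti-PD-1"] * config.n_treated + ["IgG"] * config.n_control
    for i, arm in enumerate(arms):
        tumor_id = f"T{i + 1:03d}"
        if arm == "anti-PD-1":
            u = rng.random()
            intended = (
                "DR" if u < config.p_dr else "SR" if u < config.p_dr + config.p_sr else "NR"
            )
        else:
            intended = "NR"
        rate = np.full(days.shape, config.growth_rate)
        if intended == "DR":
            rate[days >= config.response_onset_day] = -config.shrink_rate
        elif intended == "SR":
            relapse_day = rng.uniform(20, 45)
            shrinking = (days >= config.response_onset_day) & (days < relapse_day)
            rate[shrinking] = -config.shrink_rate
            rate[days >= relapse_day] = config.relapse_rate
        # integrate the piecewise rate between measurement days
        log_v = math.log(config.baseline_mm3) + np.concatenate(
            ([0.0], np.cumsum(rate[:-1] * np.diff(days)))
        )
        noise = rng.normal(0.0, config.noise_sdlog, days.size)
        noise[0] = 0.0  # baseline is the reference measurement
        volumes = np.exp(log_v + noise)
        category = _classify_trajectory(days, volumes)

        reached = np.where(volumes >= ENDPOINT_MM3)[0]
        if reached.size:
            event, time = 1, int(days[reached[0]])
            keep = slice(0, reached[0] + 1)
        else:
            event, time = 0, int(days[-1])
            keep = slice(None)
        dim = np.cbrt(6.0 * volumes[keep] / math.pi)
        for d, v, x in zip(days[keep], volumes[keep], dim):
            growth_rows.append(
                {
                    "tumor_id": tumor_id,
                    "day": int(d),
                    "L": x,
                    "W": x,
                    "D": x,
                    "volume": v,
                    "arm": arm,
                    "response_category": category,
                }
            )
        survival_rows.append(
            {"subject_id": tumor_id, "time": time, "event": event, "group": arm}
        )
    return pd.DataFrame(growth_rows), pd.DataFrame(survival_rows)


def generate_toy_proteome(
    n_proteins: int = 3, length: int = 40, n_mutations: int = 5, seed: int = 0
) -> tuple[dict[str, str], pd.DataFrame]:
    """Random toy proteins plus missense mutations for the neo-antigen stage."""
    rng = np.random.default_rng(seed)
    aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    proteins = {
        f"P{i + 1}": "".join(rng.choice(aas, length)) for i in range(n_proteins)
    }
    rows = []
    ids = list(proteins)
    for _ in range(n_mutations):
        pid = ids[rng.integers(len(ids))]
        pos = int(rng.integers(1, length + 1))
        ref = proteins[pid][pos - 1]
        alt = str(rng.choice(aas[aas != ref]))
        rows.append(
            {"protein_id": pid, "position": pos, "ref_aa": ref, "alt_aa": alt}
        )
    return proteins, pd.DataFrame(rows)


def write_cohort(cohort: dict, outdir: str | Path) -> None:
    """Write a simulated cohort in the exact formats the pipeline consumes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_expression_matrix(cohort["counts"], outdir / "counts.tsv")
    cohort["gene_lengths"].rename_axis("gene_id").to_csv(
        outdir / "gene_lengths.tsv", sep="\t", header=["length_bp"]
    )
    cohort["samples"].to_csv(outdir / "samples.tsv", sep="\t", index=False)
    write_gmt(cohort["gene_sets"], outdir / "gene_sets.gmt")
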