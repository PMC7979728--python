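"""Synthetic-data generators with known ground truth.

Every downstream stage of the package is exercisable without any
external download: this module fabricates (a) single-cell CDK2/H2B
traces with planted escape times and division events, (b) binary
marker-gene detection matrices drawn from the two-state detection model,
(c) two-condition UMI count matrices with planted differential genes,
mitochondrial genes, QC-violating outlier cells and duplicate-symbol
rows, and (d) survival cohorts with planted per-gene hazard effects.

Each generator takes a frozen config carrying its own ``rng_seed`` and
draws from a single ``numpy.random.default_rng`` stream in documented
per-cell (or per-gene, then per-cell) order, so outputs are
bit-reproducible.

Trace archetypes follow the live-imaging design of the study system
(15-min frames, drug added after an untreated baseline): every cell
cycles at high CDK2 activity before drug addition and divides at the
drug-addition frame; non-escapees then stay at the CDK2-low level,
escapees ramp linearly from low to peak over a fixed rise time starting
at their drawn escape time and divide when the ramp peaks; apoptotic
cells are represented as traces truncated before the movie ends
(tracking loss), since downstream analysis excludes rather than models
them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .posterior import DetectionMatrix, load_panel
from .scqc import CountMatrix
from .traces import Trace, TraceSet

__all__ = [
    "TraceSimConfig",
    "DetectionSimConfig",
    "CountsSimConfig",
    "CohortSimConfig",
    "simulate_traces",
    "simulate_detection_matrix",
    "simulate_counts",
    "simulate_cohort",
]


def _check_fraction(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class TraceSimConfig:
    """Live-imaging simulation: 15-min frames, 18 h untreated baseline
    then 96 h of drug, matching the study's movie design."""

    n_cells: int = 500
    frame_interval_h: float = 0.25
    movie_length_h: float = 114.0
    drug_add_h: float = 18.0
    frac_escapee: float = 0.43
    frac_apoptotic: float = 0.15
    escape_time_dist: tuple[float, float] = (40.0, 20.0)  # mean, sd (h post-drug)
    cdk2_low_level: float = 0.5
    cdk2_peak_level: float = 1.2
    cdk2_cycling_level: float = 1.0
    rise_time_h: float = 10.0
    noise_sd: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        _check_fraction("frac_escapee", self.frac_escapee)
        _check_fraction("frac_apoptotic", self.frac_apoptotic)
        if self.frac_escapee + self.frac_apoptotic > 1.0:
            raise ValueError("fractions sum above 1")
        if self.movie_length_h <= self.drug_add_h:
            raise ValueError("movie_length_h must exceed drug_add_h")
        for name in ("movie_length_h", "drug_add_h"):
            frames = getattr(self, name) / self.frame_interval_h
            if abs(frames - round(frames)) > 1e-9:
                raise ValueError(f"{name} not integral on the frame grid")

    @property
    def n_frames(self) -> int:
        return round(self.movie_length_h / self.frame_interval_h)

    @property
    def drug_add_frame(self) -> int:
        return round(self.drug_add_h / self.frame_interval_h)


def simulate_traces(cfg: TraceSimConfig) -> tuple[TraceSet, pd.DataFrame]:
    """Generate CDK2/H2B traces plus a ground-truth table.

    Per-cell RNG order: class label, escape delay (escapees), truncation
    frame (apoptotic), CDK2 noise vector, H2B noise vector.  Ground truth
    records the class, the escape frame (ramp start) and the planted
    mitosis frames (which always carry an H2B local maximum).
    """
    rng = np.random.default_rng(cfg.rng_seed)
    fi = cfg.frame_interval_h
    n_frames, drug_frame = cfg.n_frames, cfg.drug_add_frame
    rise_frames = max(1, round(cfg.rise_time_h / fi))
    # Escape delays are truncated so the planted re-entry is observable by
    # the trace rules: at least 6 h of quiescence (above the 4-h
    # short-gap conversion) and >= 6 h of ramp left before movie end
    # (tail-threshold crossing at minimum).
    max_delay_h = cfg.movie_length_h - cfg.drug_add_h - 6.0
    min_delay_h = 6.0

    traces, truth = [], []
    for i in range(cfg.n_cells):
        u = rng.random()
        if u < cfg.frac_escapee:
            label = "escapee"
        elif u < cfg.frac_escapee + cfg.frac_apoptotic:
            label = "apoptotic"
        else:
            label = "non-escapee"

        cdk2 = np.full(n_frames, cfg.cdk2_low_level)
        cdk2[:drug_frame] = cfg.cdk2_cycling_level
        h2b = np.ones(n_frames)
        h2b[drug_frame] = 2.0  # division completing at drug addition
        mitoses = [drug_frame]
        escape_frame: int | None = None
        trunc_frame: int | None = None

        if label == "escapee":
            mean, sd = cfg.escape_time_dist
            delay = float(np.clip(rng.normal(mean, sd), min_delay_h, max_delay_h))
            escape_frame = drug_frame + round(delay / fi)
            ramp_end = min(escape_frame + rise_frames, n_frames - 1)
            k = np.arange(ramp_end - escape_frame + 1)
            step = (cfg.cdk2_peak_level - cfg.cdk2_low_level) / rise_frames
            cdk2[escape_frame: ramp_end + 1] = cfg.cdk2_low_level + k * step
            if escape_frame + rise_frames <= n_frames - 1:
                h2b[ramp_end] = 2.0  # division at ramp peak, then reset
                mitoses.append(ramp_end)
                cdk2[ramp_end + 1:] = cfg.cdk2_low_level
        elif label == "apoptotic":
            trunc_frame = int(rng.integers(drug_frame + 8, n_frames - 8))

        if cfg.noise_sd > 0:
            cdk2 = np.clip(cdk2 + rng.normal(0, cfg.noise_sd, n_frames), 0, None)
            h2b = np.clip(h2b + rng.normal(0, cfg.noise_sd, n_frames), 0, None)
        else:
            rng.normal(0, 1.0, 2 * n_frames)  # keep stream order stable

        if trunc_frame is not None:
            cdk2, h2b = cdk2[:trunc_frame], h2b[:trunc_frame]
            mitoses = [m for m in mitoses if m < trunc_frame]
        traces.append(Trace(cdk2, h2b, complete=trunc_frame is None))
        truth.append({
            "cell_id": f"cell_{i:04d}", "label": label,
            "escape_frame": escape_frame,
            "mitosis_frames": mitoses,
            "truncation_frame": trunc_frame,
        })

    ts = TraceSet(traces, fi, drug_frame, [t["cell_id"] for t in truth])
    return ts, pd.DataFrame(truth)


@dataclass(frozen=True)
class DetectionSimConfig:
    """Two-state detection model: a cell is proliferative with prior
    ``p0_true``; gene i is then detected Bernoulli(p_i_true[i]), else
    Bernoulli(epsilon_true), independently across genes."""

    n_cells: int = 1000
    n_marker_genes: int = 51
    p0_true: float = 0.18  # drug-treated prior; untreated is 0.95
    p_i_true: np.ndarray | None = None  # default drawn U(0.3, 0.9)
    epsilon_true: float = 0.01
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p0_true <= 1.0:
            raise ValueError("p0_true must lie in [0, 1]")
        if not 0.0 <= self.epsilon_true < 1.0:
            raise ValueError("epsilon_true must lie in [0, 1)")
        if self.p_i_true is not None:
            p = np.asarray(self.p_i_true, dtype=float)
            if p.size != self.n_marker_genes:
                raise ValueError("p_i_true length != n_marker_genes")
            if ((p < 0) | (p > 1)).any():
                raise ValueError("p_i_true entries must lie in [0, 1]")
            object.__setattr__(self, "p_i_true", p)


def simulate_detection_matrix(
    cfg: DetectionSimConfig,
) -> tuple[DetectionMatrix, np.ndarray]:
    """Draw a binary detection matrix; returns it with the true per-cell
    proliferative state.  RNG order: p_i (when not supplied), states,
    detection matrix."""
    rng = np.random.default_rng(cfg.rng_seed)
    p = (rng.uniform(0.3, 0.9, cfg.n_marker_genes)
         if cfg.p_i_true is None else cfg.p_i_true)
    states = rng.random(cfg.n_cells) < cfg.p0_true
    probs = np.where(states[:, None], p[None, :], cfg.epsilon_true)
    x = (rng.random((cfg.n_cells, cfg.n_marker_genes)) < probs).astype(np.uint8)
    panel = load_panel()
    genes = (panel if cfg.n_marker_genes == len(panel)
             else [f"MARKER{i:03d}" for i in range(cfg.n_marker_genes)])
    return DetectionMatrix(x, genes), states


@dataclass(frozen=True)
class CountsSimConfig:
    """Two-condition UMI count matrix with planted structure.

    Marker-panel counts follow the detection model (count > 0 iff
    detected; magnitude 1 + Poisson so detection and abundance decouple);
    background counts are negative binomial.  Planted artifacts: DE genes
    (fold change applied in the treated condition), mitochondrial genes,
    low-library and high-mito outlier cells, duplicate-symbol gene rows,
    and an unequal sequencing-depth factor between conditions.
    """

    n_cells: tuple[int, int] = (300, 300)       # (untreated, treated)
    conditions: tuple[str, str] = ("untreated", "treated")
    n_background_genes: int = 600
    p0: tuple[float, float] = (0.95, 0.18)      # per-condition priors
    epsilon: float = 0.01
    marker_mean: float = 1.0                    # Poisson part of marker counts
    nb_mean: float = 2.0
    nb_dispersion: float = 0.5                  # var = mu + dispersion * mu^2
    n_de_genes: int = 20
    de_fold_change: float = 4.0
    n_mito_genes: int = 10
    mito_mean: float = 10.0
    n_low_lib_outliers: int = 2
    low_lib_factor: float = 0.02
    n_high_mito_outliers: int = 2
    high_mito_boost: float = 40.0
    n_duplicate_symbols: int = 2
    depth_factor: float = 2.0                   # untreated sequenced deeper
    marker_genes: tuple[str, ...] = field(default_factory=lambda: tuple(load_panel()))
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for p in self.p0:
            _check_fraction("p0", p)
        if self.n_de_genes + self.n_mito_genes + self.n_duplicate_symbols > self.n_background_genes:
            raise ValueError("planted gene roles exceed background genes")
        if self.n_low_lib_outliers + self.n_high_mito_outliers > min(self.n_cells):
            raise ValueError("planted outliers exceed cells per condition")


def simulate_counts(cfg: CountsSimConfig) -> tuple[CountMatrix, dict]:
    """Generate the count matrix plus a ground-truth dict.

    Gene layout: marker panel first, then background genes; DE,
    mitochondrial and duplicate-symbol roles are assigned to disjoint
    leading slices of the background block, so overlapping role
    assignments are impossible by construction.  RNG order: background
    means, detection states/matrix per condition, marker magnitudes,
    background counts, outlier draws.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    markers = list(cfg.marker_genes)
    n_mark, n_bg = len(markers), cfg.n_background_genes

    de_idx = np.arange(cfg.n_de_genes)
    mito_idx = np.arange(cfg.n_de_genes, cfg.n_de_genes + cfg.n_mito_genes)
    dup_idx = np.arange(cfg.n_de_genes + cfg.n_mito_genes,
                        cfg.n_de_genes + cfg.n_mito_genes + cfg.n_duplicate_symbols)

    bg_symbols = [f"BG{i:04d}" for i in range(n_bg)]
    for j, g in enumerate(mito_idx):
        bg_symbols[g] = f"MT-SYN{j}"
    symbols = markers + bg_symbols
    gene_ids = [f"ENSG{i:05d}" for i in range(n_mark + n_bg)]

    bg_mu = rng.lognormal(np.log(cfg.nb_mean), 0.5, n_bg)

    blocks, cell_ids, cond_labels, states_all = [], [], [], []
    for ci, (cond, n_cells, p0) in enumerate(
            zip(cfg.conditions, cfg.n_cells, cfg.p0)):
        depth = cfg.depth_factor if ci == 0 else 1.0
        states = rng.random(n_cells) < p0
        p_i = rng.uniform(0.3, 0.9, n_mark)
        det_p = np.where(states[None, :], p_i[:, None], cfg.epsilon)
        detected = rng.random((n_mark, n_cells)) < det_p
        magnitude = 1 + rng.poisson(cfg.marker_mean * depth, (n_mark, n_cells))
        marker_counts = detected * magnitude

        mu = np.tile(bg_mu[:, None], (1, n_cells)) * depth
        if ci == 1:
            mu[de_idx, :] *= cfg.de_fold_change
        mu[mito_idx, :] = cfg.mito_mean * depth
        # NB via gamma-Poisson: shape r = 1/dispersion
        r = 1.0 / cfg.nb_dispersion
        lam = rng.gamma(r, mu / r)
        bg_counts = rng.poisson(lam)

        block = np.vstack([marker_counts, bg_counts])
        blocks.append(block)
        cell_ids += [f"{cond}_{i:04d}" for i in range(n_cells)]
        cond_labels += [cond] * n_cells
        states_all.append(states)

    counts = np.hstack(blocks)

    # planted outlier cells, drawn from the treated condition
    n0 = cfg.n_cells[0]
    low_cells = list(range(n0, n0 + cfg.n_low_lib_outliers))
    high_cells = list(range(n0 + cfg.n_low_lib_outliers,
                            n0 + cfg.n_low_lib_outliers + cfg.n_high_mito_outliers))
    for c in low_cells:
        counts[:, c] = rng.binomial(counts[:, c], cfg.low_lib_factor)
    mito_rows = n_mark + mito_idx
    for c in high_cells:
        counts[mito_rows, c] += rng.poisson(cfg.high_mito_boost, mito_rows.size)

    # duplicate-symbol rows: a second gene ID sharing an existing symbol
    extra_rows, extra_ids, extra_syms = [], [], []
    for j, g in enumerate(dup_idx):
        extra_rows.append(counts[n_mark + g, :])
        extra_ids.append(f"ENSGDUP{j:02d}")
        extra_syms.append(symbols[n_mark + g])
    if extra_rows:
        counts = np.vstack([counts, np.array(extra_rows)])
        gene_ids += extra_ids
        symbols += extra_syms

    cm = CountMatrix(counts, gene_ids, symbols, cell_ids, np.asarray(cond_labels))
    truth = {
        "marker_gene_ids": gene_ids[:n_mark],
        "de_gene_ids": [gene_ids[n_mark + g] for g in de_idx],
        "mito_gene_ids": [gene_ids[n_mark + g] for g in mito_idx],
        "duplicate_symbols": extra_syms,
        "low_lib_cell_ids": [cell_ids[c] for c in low_cells],
        "high_mito_cell_ids": [cell_ids[c] for c in high_cells],
        "proliferative": np.concatenate(states_all),
    }
    return cm, truth


@dataclass(frozen=True)
class CohortSimConfig:
    """Survival cohort with exponential event times: per-patient hazard
    baseline_hazard * exp(covariate effects + sum_g log_hr[g] * expr_g),
    independent exponential censoring, log-normal expression."""

    n_patients: int = 500
    n_genes: int = 20
    baseline_hazard: float = 0.02
    censor_rate: float = 0.01
    log_hr_per_gene: tuple[float, ...] | None = None  # default all zero
    covariate_effects: tuple[float, float, float] = (0.02, 0.1, 0.3)
    expr_sigma: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be >= 0")
        if self.log_hr_per_gene is not None and len(self.log_hr_per_gene) != self.n_genes:
            raise ValueError("log_hr_per_gene length != n_genes")


def simulate_cohort(cfg: CohortSimConfig) -> pd.DataFrame:
    """Generate a survival cohort table.

    Columns: patient_id, time, event, age, gender, stage, then one column
    per gene (G000...).  RNG order: age, gender, stage, expression,
    event times, censor times.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    n, g = cfg.n_patients, cfg.n_genes
    log_hr = np.zeros(g) if cfg.log_hr_per_gene is None else np.asarray(cfg.log_hr_per_gene)

    age = np.clip(rng.normal(60, 10, n), 25, 90)
    gender = rng.integers(0, 2, n)
    stage = rng.integers(1, 5, n)
    expr = rng.lognormal(0.0, cfg.expr_sigma, (n, g))

    b_age, b_gender, b_stage = cfg.covariate_effects
    lp = (b_age * (age - 60) / 10 + b_gender * gender + b_stage * (stage - 2)
          + (expr - np.exp(cfg.expr_sigma ** 2 / 2)) @ log_hr)
    hazard = cfg.baseline_hazard * np.exp(lp)
    t_event = rng.exponential(1.0 / hazard)
    if cfg.censor_rate > 0:
        t_cens = rng.exponential(1.0 / cfg.censor_rate, n)
    else:
        t_cens = np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    df = pd.DataFrame({
        "patient_id": [f"P{i:04d}" for i in range(n)],
        "time": np.maximum(time, 1e-6),
        "event": event,
        "age": age,
        "gender": np.where(gender == 1, "male", "female"),
        "stage": stage,
    })
    for j in range(g):
        df[f"G{j:03d}"] = expr[:, j]
    return df
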