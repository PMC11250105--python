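"""Synthetic islet donor cohorts: metadata, perifusion traces, paired omics.

The generator emulates the statistical structure of a human-islet
deep-phenotyping cohort so that every downstream analysis stage can be
exercised and validated against known ground truth:

* three-arm perifusion traces with biphasic glucose/leucine responses,
  monophasic fat responses and sharp KCl transients;
* donor heterogeneity, with configurable subpopulations of fat and protein
  (leucine) hyper-responders whose nutrient AUC exceeds their 15 mM glucose
  AUC;
* stimulus-specific multiplicative secretion deficits in T2D donors plus a
  delayed high-glucose time-to-peak;
* paired proteome (log-normal intensities, planted co-expression modules
  coupled to functional traits, T2D-differential features,
  abundance-dependent missingness) and transcriptome (negative-binomial
  counts, batch location/scale effects, T2D-differential genes) matrices with
  a configurable across-gene RNA-protein correlation of means.

Every latent draw is recorded in ground-truth tables that analysis stages
never consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .perifusion import UNIT_CONC, PerifusionTrace
from .protocol import StimulusProtocol, canonical_protocols, write_protocol_yaml

__all__ = [
    "GeneratorConfig",
    "CohortBundle",
    "simulate_cohort",
    "simulate_trace",
    "simulate_omics",
    "write_cohort",
    "shape_value",
    "shape_integral",
]


class ConfigurationError(ValueError):
    """Invalid generator configuration; the message names the field."""


# ---------------------------------------------------------------------------
# configuration

_DEFAULT_T2D_EFFECT = {
    "glucose15": 0.60,
    "glucose6": 0.65,
    "fat": 0.45,
    "kcl": 0.78,
    "leucine": 1.00,
    "leu_plus_g6": 0.64,
    "fat_plus_g6": 0.45,
}

_DEFAULT_COUPLING = {
    0: ("auc_fat", 0.6),
    1: ("auc_glucose15", 0.5),
    2: ("auc_leucine", 0.5),
    3: ("hba1c", -0.4),
}

_CELL_TYPES = ("beta", "alpha", "delta", "acinar")
_COMPOSITION_ND = np.array([0.55, 0.30, 0.08, 0.07])
_COMPOSITION_T2D = np.array([0.44, 0.36, 0.08, 0.12])


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort generator.

    The defaults are the study conditions: a 123 ND / 17 T2D cohort, 8% fat
    and 9% protein hyper-responder prevalence, stimulus-specific T2D
    secretion multipliers (0.60 for 15 mM glucose, 0.65 for 6 mM glucose,
    0.45 for fat, 0.78 for KCl, 1.00 for leucine alone, 0.64 for leucine +
    6 mM glucose), a 3-min T2D high-glucose peak delay, 10% multiplicative
    assay CV averaged over two technical replicates, a 2,000-protein /
    3,000-gene paired omics panel with 18 planted co-expression modules, and
    an across-gene RNA-protein correlation target of 0.5.
    """

    n_nd: int = 123
    n_t2d: int = 17
    pi_fat: float = 0.08
    pi_leu: float = 0.09
    t2d_effect: dict = field(default_factory=lambda: dict(_DEFAULT_T2D_EFFECT))
    t2d_peak_delay_min: float = 3.0
    capacity_cv: float = 0.25
    response_cv: float = 0.2
    assay_cv: float = 0.10
    n_tech_reps: int = 2
    baseline_rate: float = 0.08       # pmol/islet/min at 3 mM glucose
    sampling_interval: float = 1.0    # min
    hr_ratio_range: tuple = (1.1, 1.6)
    hr_kcl_factor: float = 0.7
    # omics
    n_proteins: int = 2000
    n_genes: int = 3000
    n_modules: int = 18
    module_size_range: tuple = (50, 110)
    module_loading_range: tuple = (0.25, 0.45)
    module_trait_coupling: dict = field(default_factory=lambda: dict(_DEFAULT_COUPLING))
    n_de_protein_up: int = 100
    n_de_protein_down: int = 100
    n_de_rna_up: int = 150
    n_de_rna_down: int = 150
    de_log2fc: float = 0.5
    rna_protein_r: float = 0.5
    protein_noise_sd: float = 0.12    # log10 residual SD
    gene_level_sd: float = 0.7        # log10 spread of protein means
    n_batches: int = 4
    batch_shift_sd: float = 0.25      # log2 location shift of RNA means
    missing_frac: float = 0.05
    high_missing_frac_features: float = 0.02
    high_missing_rate: float = 0.6
    dispersion_range: tuple = (0.1, 0.5)
    lib_size: float = 2.0e6
    lib_cv: float = 0.3
    n_markers_per_type: int = 8
    marker_effect: float = 1.2
    seed: int = 0

    def validate(self) -> None:
        for name in ("pi_fat", "pi_leu", "missing_frac",
                     "high_missing_frac_features"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        for key, mult in self.t2d_effect.items():
            if not mult > 0:
                raise ConfigurationError(
                    f"t2d_effect[{key!r}] must be > 0, got {mult}")
        if self.pi_fat + self.pi_leu > 1.0:
            raise ConfigurationError("pi_fat + pi_leu must not exceed 1")
        for name in ("n_nd", "n_t2d", "n_tech_reps", "n_proteins", "n_genes",
                     "n_batches"):
            if getattr(self, name) < 0 or (name == "n_tech_reps"
                                           and getattr(self, name) < 1):
                raise ConfigurationError(f"{name} must be non-negative")
        if self.n_modules < 1:
            raise ConfigurationError("n_modules must be >= 1")
        if self.n_modules * self.module_size_range[1] > self.n_proteins:
            raise ConfigurationError(
                "module_size_range: maximal total module size exceeds n_proteins")
        for name in ("capacity_cv", "response_cv", "assay_cv"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not -1.0 <= self.rna_protein_r <= 1.0:
            raise ConfigurationError("rna_protein_r must be in [-1, 1]")


# ---------------------------------------------------------------------------
# kinetic shapes

# per-stimulus response shape parameters, in units of the basal rate:
# a first-phase alpha-function pulse (t/tau)e^{1-t/tau} plus a saturating
# second-phase plateau 1-e^{-t/tau}; fat is plateau-only (monophasic), KCl a
# sharp pulse.
SHAPES = {
    "glucose15": dict(pulse=6.0, tau_pulse=4.0, plat=3.0, tau_plat=10.0),
    "glucose6": dict(pulse=2.5, tau_pulse=4.0, plat=1.5, tau_plat=10.0),
    "leucine": dict(pulse=2.0, tau_pulse=4.0, plat=1.1, tau_plat=10.0),
    "leu_plus_g6": dict(pulse=3.0, tau_pulse=4.0, plat=1.6, tau_plat=10.0),
    "fat": dict(pulse=0.0, tau_pulse=4.0, plat=1.2, tau_plat=15.0),
    "fat_plus_g6": dict(pulse=0.0, tau_pulse=4.0, plat=1.5, tau_plat=15.0),
    "kcl": dict(pulse=8.0, tau_pulse=2.0, plat=0.0, tau_plat=10.0),
}


def _alpha(t: np.ndarray, tau: float) -> np.ndarray:
    t = np.maximum(t, 0.0)
    return (t / tau) * np.exp(1.0 - t / tau)


def _sat(t: np.ndarray, tau: float) -> np.ndarray:
    t = np.maximum(t, 0.0)
    return 1.0 - np.exp(-t / tau)


def _alpha_integral(T: float, tau: float) -> float:
    if T <= 0:
        return 0.0
    x = T / tau
    return float(np.e * tau * (1.0 - np.exp(-x) * (1.0 + x)))


def _sat_integral(T: float, tau: float) -> float:
    if T <= 0:
        return 0.0
    return float(T - tau * (1.0 - np.exp(-T / tau)))


def shape_value(stimulus: str, t: np.ndarray, delay: float = 0.0,
                duration: float | None = None) -> np.ndarray:
    """Relative response shape at time t (min) after segment start.

    A delayed shape is shifted right and rescaled so its integral over the
    segment is unchanged (the delay moves the peak, not the dose).
    """
    p = SHAPES[stimulus]
    td = t - delay
    v = p["pulse"] * _alpha(td, p["tau_pulse"]) + p["plat"] * _sat(td, p["tau_plat"])
    if delay > 0.0:
        if duration is None:
            raise ValueError("duration required to renormalize a delayed shape")
        full = shape_integral(stimulus, duration)
        shifted = shape_integral(stimulus, duration - delay)
        if shifted > 0:
            v = v * (full / shifted)
    return v


def shape_integral(stimulus: str, duration: float) -> float:
    """Integral of the relative shape over a segment of the given length."""
    p = SHAPES[stimulus]
    return (p["pulse"] * _alpha_integral(duration, p["tau_pulse"])
            + p["plat"] * _sat_integral(duration, p["tau_plat"]))


# ---------------------------------------------------------------------------
# donors

def _lognormal_mean1(rng: np.random.Generator, cv: float, size=None) -> np.ndarray:
    """Multiplicative log-normal noise with mean exactly 1."""
    if cv == 0:
        return np.ones(size) if size is not None else np.float64(1.0)
    s2 = np.log1p(cv * cv)
    return rng.lognormal(-0.5 * s2, np.sqrt(s2), size)


def _simulate_donors(config: GeneratorConfig, rng: np.random.Generator
                     ) -> pd.DataFrame:
    n = config.n_nd + config.n_t2d
    group = np.array(["ND"] * config.n_nd + ["T2D"] * config.n_t2d)
    donor_id = np.array([f"D{i:03d}" for i in range(n)])
    sex = rng.choice(["F", "M"], n)
    age = np.clip(rng.normal(55, 13, n), 20, 85).round(0)
    bmi = np.clip(rng.lognormal(np.log(27), 0.17, n), 17, 50).round(1)
    hba1c = np.where(
        group == "T2D",
        np.clip(rng.normal(7.6, 1.1, n), 6.0, 12.0),
        np.clip(rng.normal(5.4, 0.35, n), 4.4, 6.3),
    ).round(1)
    culture_time = np.clip(rng.lognormal(np.log(48), 0.5, n), 12, 180).round(0)
    cold_ischemia_time = np.clip(rng.normal(10, 4, n), 2, 24).round(1)
    digestion_time = np.clip(rng.normal(14, 3, n), 8, 25).round(1)
    purity = np.clip(rng.beta(17, 3, n), 0.4, 0.99).round(2)

    u = rng.random(n)
    latent_class = np.where(
        u < config.pi_fat, "fat_hr",
        np.where(u < config.pi_fat + config.pi_leu, "leu_hr", "typical"),
    )
    capacity = _lognormal_mean1(rng, config.capacity_cv, n)
    lo, hi = config.hr_ratio_range
    hr_ratio = np.where(latent_class == "typical", np.nan,
                        rng.uniform(lo, hi, n))

    df = pd.DataFrame({
        "donor_id": donor_id, "group": group, "sex": sex, "age": age,
        "bmi": bmi, "hba1c": hba1c, "culture_time": culture_time,
        "cold_ischemia_time": cold_ischemia_time,
        "digestion_time": digestion_time, "purity": purity,
        "islet_count": 65, "latent_class": latent_class,
        "capacity": capacity, "hr_ratio": hr_ratio,
    })
    for stim in SHAPES:
        df[f"jitter_{stim}"] = _lognormal_mean1(rng, config.response_cv, n)
    return df


def _amplitude_factors(donor: pd.Series, config: GeneratorConfig
                       ) -> dict[str, float]:
    """Per-stimulus multiplicative amplitude for one donor.

    Combines the per-donor response jitter, the hyper-responder rescaling
    (solved so that the noise-free nutrient AUC is ``hr_ratio`` times the
    noise-free 15 mM glucose AUC, before T2D multipliers) and the
    stimulus-specific T2D multiplier.
    """
    g15_auc = donor["jitter_glucose15"] * shape_integral("glucose15", 40.0)
    factors = {}
    for stim in SHAPES:
        f = donor[f"jitter_{stim}"]
        if donor["latent_class"] == "fat_hr":
            if stim in ("fat", "fat_plus_g6"):
                base = donor["jitter_fat"] * shape_integral("fat", 40.0)
                f = f * donor["hr_ratio"] * g15_auc / base
            elif stim == "kcl":
                f = f * config.hr_kcl_factor
        elif donor["latent_class"] == "leu_hr":
            # the protein hyper-response is defined (and documented) for the
            # nutrient-at-basal-glucose challenge only
            if stim == "leucine":
                base = donor["jitter_leucine"] * shape_integral("leucine", 40.0)
                f = f * donor["hr_ratio"] * g15_auc / base
        if donor["group"] == "T2D":
            f = f * config.t2d_effect.get(stim, 1.0)
        factors[stim] = float(f)
    return factors


def simulate_trace(donor: pd.Series, arm: str, protocol: StimulusProtocol,
                   config: GeneratorConfig, rng: np.random.Generator,
                   ) -> PerifusionTrace:
    """Simulate one donor-arm effluent concentration trace (pmol/mL)."""
    t = np.arange(0.0, protocol.end_min + 1e-9, config.sampling_interval)
    factors = _amplitude_factors(donor, config)
    rel = np.zeros_like(t)
    for seg in protocol.segments:
        if seg.stimulus in ("basal", "washout"):
            continue
        delay = (config.t2d_peak_delay_min
                 if donor["group"] == "T2D" and seg.stimulus == "glucose15"
                 else 0.0)
        inseg = (t >= seg.start_min) & (t <= seg.end_min)
        rel[inseg] += factors[seg.stimulus] * shape_value(
            seg.stimulus, t[inseg] - seg.start_min, delay=delay,
            duration=seg.duration)
    rate = config.baseline_rate * donor["capacity"] * (1.0 + rel)
    conc = rate * 65.0 / 0.4  # pmol/mL effluent at 0.4 mL/min, 65 islets
    noise = _lognormal_mean1(rng, config.assay_cv,
                             (config.n_tech_reps, t.size)).mean(axis=0)
    return PerifusionTrace(
        donor_id=donor["donor_id"], arm=arm, time_min=t, values=conc * noise,
        unit=UNIT_CONC, protocol=protocol, islet_count=65.0, flow_rate=0.4,
    )


def _true_aucs(donors: pd.DataFrame, config: GeneratorConfig,
               protocols: dict[str, StimulusProtocol]) -> pd.DataFrame:
    """Noise-free baseline-subtracted AUC of every stimulus segment."""
    out = {}
    segs = [(p[s.name], s.name) for p in protocols.values()
            for s in p.stimulus_segments]
    for seg, name in segs:
        vals = []
        for _, donor in donors.iterrows():
            f = _amplitude_factors(donor, config)[seg.stimulus]
            auc = (config.baseline_rate * donor["capacity"] * f
                   * shape_integral(seg.stimulus, seg.duration))
            vals.append(auc)
        out[f"auc_{name}_true"] = vals
    return pd.DataFrame(out, index=donors.index)


# ---------------------------------------------------------------------------
# omics

def _trait_vector(donors: pd.DataFrame, trait: str) -> np.ndarray:
    if trait.startswith("auc_") and not trait.endswith("_true"):
        col = f"{trait}_true"
    else:
        col = trait
    v = donors[col].to_numpy(dtype=float)
    if trait.startswith("auc_"):
        v = np.log10(np.maximum(v, 1e-12))
    sd = v.std()
    return (v - v.mean()) / (sd if sd > 0 else 1.0)


def simulate_omics(donors: pd.DataFrame, config: GeneratorConfig,
                   rng: np.random.Generator,
                   ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Paired proteome and transcriptome matrices for a simulated cohort.

    Returns ``(protein, rna, truth)``: a features x donors raw-intensity
    protein matrix (missing entries NaN), a genes x donors integer count
    matrix, and ground-truth tables (protein/gene feature annotation, donor
    batch and cell-composition draws, marker sets).
    """
    config.validate()
    n = len(donors)
    n_p, n_g = config.n_proteins, config.n_genes
    if n_p > n_g:
        raise ConfigurationError("n_proteins must not exceed n_genes")
    donor_ids = donors["donor_id"].to_numpy()
    t2d = (donors["group"] == "T2D").to_numpy()

    gene_ids = np.array([f"G{i:04d}" for i in range(n_g)])
    prot_ids = np.array([f"P{i:04d}" for i in range(n_p)])

    # shared gene-level component sets the across-gene correlation of means
    r = config.rna_protein_r
    z = rng.standard_normal(n_g)
    e = rng.standard_normal(n_g)
    core = r * z + np.sqrt(max(0.0, 1.0 - r * r)) * e
    mu_protein = 5.5 + config.gene_level_sd * core[:n_p]          # log10
    log2_rel_rna = 2.2 * z                                        # log2, relative

    # --- planted structure bookkeeping
    module_label = np.zeros(n_p, dtype=int)
    sizes = rng.integers(config.module_size_range[0],
                         config.module_size_range[1] + 1, config.n_modules)
    pos = 0
    for m, size in enumerate(sizes, start=1):
        module_label[pos:pos + size] = m
        pos += size
    background = np.flatnonzero(module_label == 0)

    n_up, n_dn = config.n_de_protein_up, config.n_de_protein_down
    n_mark = config.n_markers_per_type * len(_CELL_TYPES)
    n_hm = int(round(config.high_missing_frac_features * n_p))
    need = n_up + n_dn + n_mark + n_hm
    if need > background.size:
        raise ConfigurationError(
            "module_size_range leaves too few background features for the "
            "planted differential/marker/missingness features")
    picks = rng.choice(background, size=need, replace=False)
    de_up, de_dn, marker_idx, hm_idx = np.split(
        picks, np.cumsum([n_up, n_dn, n_mark])[:3])
    de_sign = np.zeros(n_p)
    de_sign[de_up] = 1.0
    de_sign[de_dn] = -1.0
    # protein feature i maps to gene i, so marker indexing covers both
    marker_type = np.array([""] * n_g, dtype=object)
    for k, ct in enumerate(_CELL_TYPES):
        sel = marker_idx[k * config.n_markers_per_type:
                         (k + 1) * config.n_markers_per_type]
        marker_type[sel] = ct

    # --- donor latent structure: module factors and cell composition
    F = rng.standard_normal((config.n_modules, n))
    for m, (trait, strength) in config.module_trait_coupling.items():
        if not 0 <= m < config.n_modules:
            continue
        tv = _trait_vector(donors, trait)
        c = float(np.clip(strength, -0.99, 0.99))
        F[m] = c * tv + np.sqrt(1.0 - c * c) * rng.standard_normal(n)
    loading = rng.uniform(*config.module_loading_range, n_p)

    comp_mean = np.where(t2d[:, None], _COMPOSITION_T2D, _COMPOSITION_ND)
    composition = np.vstack([rng.dirichlet(60.0 * cm) for cm in comp_mean])
    log_comp = np.log10(np.maximum(composition, 1e-6))
    log_comp_centered = log_comp - log_comp.mean(axis=0, keepdims=True)

    # --- proteome (log10 intensities)
    P = mu_protein[:, None] + rng.normal(0.0, config.protein_noise_sd, (n_p, n))
    for m in range(1, config.n_modules + 1):
        rowsel = module_label == m
        P[rowsel] += loading[rowsel, None] * F[m - 1][None, :]
    fc10 = config.de_log2fc * np.log10(2.0)
    P += de_sign[:, None] * fc10 * t2d[None, :]
    for k, ct in enumerate(_CELL_TYPES):
        rowsel = marker_type[:n_p] == ct
        P[rowsel] += config.marker_effect * log_comp_centered[:, k][None, :]
    P += rng.normal(0.0, 0.05, n)[None, :]  # sample loading offset

    # abundance-dependent missingness + planted high-missingness features
    zscore = (P - P.mean()) / P.std()
    p_miss = 2.0 * config.missing_frac / (1.0 + np.exp(2.0 * zscore))
    mask = rng.random((n_p, n)) < p_miss
    n_miss_hm = int(round(config.high_missing_rate * n))
    for i in hm_idx:
        cols = rng.choice(n, n_miss_hm, replace=False)
        mask[i] = False
        mask[i, cols] = True
    protein = pd.DataFrame(10.0 ** P, index=prot_ids, columns=donor_ids)
    protein[pd.DataFrame(mask, index=prot_ids, columns=donor_ids)] = np.nan

    # --- transcriptome (negative binomial via gamma-Poisson)
    batches = np.array([f"B{i % config.n_batches + 1}" for i in range(n)])
    rng.shuffle(batches)
    w = 2.0 ** log2_rel_rna
    w = w / w.sum()
    lib = config.lib_size * _lognormal_mean1(rng, config.lib_cv, n)
    mu = w[:, None] * lib[None, :]
    batch_shift = rng.normal(0.0, config.batch_shift_sd,
                             (n_g, config.n_batches))
    batch_scale = rng.uniform(0.8, 1.25, config.n_batches)
    b_of = np.array([int(b[1:]) - 1 for b in batches])
    mu = mu * 2.0 ** batch_shift[:, b_of]
    rna_de_sign = np.zeros(n_g)
    # plant RNA DE in the same genes as protein DE where possible, topped up
    # from mid-expressed genes so planted effects survive the low-count filter
    rna_de_sign[de_up] = 1.0
    rna_de_sign[de_dn] = -1.0
    mid = np.flatnonzero((np.abs(z) < 1.0) & (rna_de_sign == 0)
                         & (np.arange(n_g) >= n_p))
    extra_up = max(0, config.n_de_rna_up - n_up)
    extra_dn = max(0, config.n_de_rna_down - n_dn)
    if extra_up + extra_dn > 0 and mid.size >= extra_up + extra_dn:
        extra = rng.choice(mid, extra_up + extra_dn, replace=False)
        rna_de_sign[extra[:extra_up]] = 1.0
        rna_de_sign[extra[extra_up:]] = -1.0
    mu = mu * 2.0 ** (config.de_log2fc * rna_de_sign[:, None] * t2d[None, :])
    for k, ct in enumerate(_CELL_TYPES):
        rowsel = marker_type == ct
        mu[rowsel] *= 10.0 ** (config.marker_effect
                               * log_comp_centered[:, k][None, :])
    disp = rng.uniform(*config.dispersion_range, n_g)
    disp_dc = disp[:, None] * batch_scale[b_of][None, :]
    shape = 1.0 / disp_dc
    lam = rng.gamma(shape, mu * disp_dc)
    counts = rng.poisson(lam).astype(np.int64)
    rna = pd.DataFrame(counts, index=gene_ids, columns=donor_ids)

    protein_truth = pd.DataFrame({
        "feature_id": prot_ids, "gene_id": gene_ids[:n_p],
        "module": module_label, "loading": loading, "de_sign": de_sign,
        "marker_type": marker_type[:n_p].astype(str),
        "high_missing": np.isin(np.arange(n_p), hm_idx),
        "mean_log10": mu_protein,
    })
    rna_truth = pd.DataFrame({
        "gene_id": gene_ids, "de_sign": rna_de_sign, "dispersion": disp,
        "marker_type": marker_type.astype(str),
        "mean_log2_rel": log2_rel_rna,
    })
    donor_omics = pd.DataFrame(
        {"donor_id": donor_ids, "batch": batches}
        | {f"frac_{ct}": composition[:, k] for k, ct in enumerate(_CELL_TYPES)}
    )
    markers = pd.DataFrame({
        "cell_type": marker_type[marker_idx].astype(str),
        "feature_id": prot_ids[marker_idx],
        "gene_id": gene_ids[marker_idx],
    })
    truth = {"protein": protein_truth, "rna": rna_truth,
             "donor_omics": donor_omics, "markers": markers,
             "factors": pd.DataFrame(
                 F.T, index=donor_ids,
                 columns=[f"factor_{m + 1}" for m in range(config.n_modules)])}
    return protein, rna, truth


# ---------------------------------------------------------------------------
# cohort bundle

@dataclass
class CohortBundle:
    """Everything one simulated cohort produced, ground truth included."""

    config: GeneratorConfig
    donors: pd.DataFrame          # analysis-facing metadata (no latents)
    donor_truth: pd.DataFrame     # latent draws + noise-free AUCs
    traces: list
    protocols: dict
    protein: pd.DataFrame | None = None
    rna: pd.DataFrame | None = None
    omics_truth: dict | None = None


_METADATA_COLS = ["donor_id", "group", "sex", "age", "bmi", "hba1c",
                  "culture_time", "cold_ischemia_time", "digestion_time",
                  "purity", "islet_count"]


def simulate_cohort(config: GeneratorConfig, omics: bool = True) -> CohortBundle:
    """Simulate a full donor cohort: metadata, three-arm traces, omics."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_donor, rng_trace, rng_omics = (np.random.default_rng(c)
                                       for c in ss.spawn(3))
    protocols = canonical_protocols()
    donors_full = _simulate_donors(config, rng_donor)
    donors_full = pd.concat(
        [donors_full, _true_aucs(donors_full, config, protocols)], axis=1)

    traces = []
    for _, donor in donors_full.iterrows():
        for arm, proto in protocols.items():
            traces.append(simulate_trace(donor, arm, proto, config, rng_trace))

    donors = donors_full[_METADATA_COLS].copy()
    truth_cols = ["donor_id", "group", "latent_class", "capacity", "hr_ratio"]
    truth_cols += [c for c in donors_full.columns
                   if c.startswith(("jitter_", "auc_"))]
    bundle = CohortBundle(
        config=config, donors=donors, donor_truth=donors_full[truth_cols],
        traces=traces, protocols=protocols,
    )
    if omics and config.n_proteins > 0:
        protein, rna, truth = simulate_omics(donors_full, config, rng_omics)
        bundle.protein, bundle.rna, bundle.omics_truth = protein, rna, truth
        bundle.donors = donors.merge(
            truth["donor_omics"][["donor_id", "batch"]], on="donor_id")
    return bundle


def write_cohort(bundle: CohortBundle, outdir) -> None:
    """Write a cohort to TSV files (long-format traces, matrices, truth)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle.donors.to_csv(outdir / "donors.tsv", sep="\t", index=False)
    bundle.donor_truth.to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
    write_protocol_yaml(bundle.protocols, outdir / "protocol.yaml")
    for arm in bundle.protocols:
        rows = []
        for tr in bundle.traces:
            if tr.arm != arm:
                continue
            seg_names = np.full(tr.time_min.shape, "", dtype=object)
            for seg in tr.protocol.segments:
                m = (tr.time_min >= seg.start_min) & (tr.time_min <= seg.end_min)
                seg_names[m] = seg.name
            rows.append(pd.DataFrame({
                "donor_id": tr.donor_id, "time_min": tr.time_min,
                "segment": seg_names, "value": tr.values, "unit": tr.unit,
                "islet_count": tr.islet_count, "flow_rate": tr.flow_rate,
            }))
        pd.concat(rows).to_csv(outdir / f"traces_{arm}.tsv", sep="\t",
                               index=False)
    if bundle.protein is not None:
        bundle.protein.to_csv(outdir / "protein_matrix.tsv", sep="\t")
        bundle.rna.to_csv(outdir / "rna_counts.tsv", sep="\t")
        bundle.omics_truth["protein"].to_csv(
            outdir / "protein_truth.tsv", sep="\t", index=False)
        bundle.omics_truth["rna"].to_csv(
            outdir / "rna_truth.tsv", sep="\t", index=False)
        bundle.omics_truth["donor_omics"].to_csv(
            outdir / "donor_omics_truth.tsv", sep="\t", index=False)
        bundle.omics_truth["markers"][["cell_type", "feature_id"]].to_csv(
            outdir / "markers.tsv", sep="\t", index=False)
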