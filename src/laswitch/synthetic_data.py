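"""Synthetic two-condition (Ca vs La) chemostat multi-omics generators.

Each generator is the measurable inverse of an analysis stage: noiseless
output lets the corresponding calculator recover the planted parameters
exactly, and noisy output recovers them within a stated tolerance.  Every
dataset carries its ground truth in a sidecar table (or ``attrs``
metadata) that the analysis stages never read.

Planted effects follow the observed La response: *xoxF* transcription up
fourfold (protein twofold), *fae2* up 14-fold, a putative sulfate
transporter up >70-fold, the *fds2* operon up threefold, the *mxaFIG*
cluster strongly down, and *xoxG4* modestly down at the transcript level
only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .physiology import CH4_MOLAR_MASS, MOLAR_VOLUME_L, ConditionSpec

__all__ = [
    "Effect",
    "EffectRegistry",
    "MetabolitePattern",
    "CONDITIONS",
    "PLANTED_PHYSIOLOGY",
    "simulate_offgas",
    "simulate_counts",
    "simulate_spectral_counts",
    "simulate_metabolites",
    "welch_de_table",
]


# ---------------------------------------------------------------------------
# study conditions (chemostat presets) and planted physiology
# ---------------------------------------------------------------------------

#: Bioreactor condition presets.  Gas supply reflects the physical
#: apparatus (0.25 L culture, 1 sL/h gas at 5%:5% or 2.5%:10% CH4:O2).
CONDITIONS: dict[str, ConditionSpec] = {
    "ca_optimal": ConditionSpec("ca_optimal", 5.0, 5.0, 1.0, 0.25, 0.64, 0.05),
    "ca_limited": ConditionSpec("ca_limited", 2.5, 10.0, 1.0, 0.25, 0.67, 0.05),
    "la_optimal": ConditionSpec("la_optimal", 5.0, 5.0, 1.0, 0.25, 0.75, 0.07),
    "la_limited": ConditionSpec("la_limited", 2.5, 10.0, 1.0, 0.25, 0.45, 0.06),
}

#: Planted (biomass yield g/g, O2:CH4 ratio) per condition; ratios were
#: only measured at optimal gas supply, so the limited presets reuse them.
PLANTED_PHYSIOLOGY: dict[str, tuple[float, float]] = {
    "ca_optimal": (1.2, 1.12),
    "ca_limited": (0.98, 1.12),
    "la_optimal": (0.64, 1.28),
    "la_limited": (0.67, 1.28),
}


# ---------------------------------------------------------------------------
# effect registry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Effect:
    transcript_fc: float     # La over Ca, linear scale
    protein_fc: float
    direction: str           # up | down | flat

    def __post_init__(self) -> None:
        if self.transcript_fc <= 0 or self.protein_fc <= 0:
            raise ValueError("fold-changes must be > 0")


def _default_effects() -> dict[str, Effect]:
    down20 = Effect(1 / 20, 1 / 20, "down")
    return {
        "xoxF": Effect(4.0, 2.0, "up"),
        "fae2": Effect(14.0, 4.0, "up"),
        "sulfate_transporter": Effect(70.0, 1.0, "up"),
        "fds2D": Effect(3.0, 1.0, "up"),
        "fds2C": Effect(3.0, 1.0, "up"),
        "fds2A": Effect(3.0, 1.0, "up"),
        "mxaF": down20,
        "mxaI": down20,
        "mxaG": down20,
        "xoxG4": Effect(1 / 1.5, 1.0, "down"),
    }


@dataclass
class EffectRegistry:
    """Ground-truth La/Ca fold-changes planted by the generators."""

    effects: dict[str, Effect] = field(default_factory=_default_effects)

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self.effects

    def transcript_fc(self, feature_id: str) -> float:
        e = self.effects.get(feature_id)
        return e.transcript_fc if e else 1.0

    def protein_fc(self, feature_id: str) -> float:
        e = self.effects.get(feature_id)
        return e.protein_fc if e else 1.0

    @classmethod
    def neutral(cls) -> "EffectRegistry":
        return cls(effects={})

    def to_frame(self) -> pd.DataFrame:
        rows = [{"feature_id": fid, "transcript_fc": e.transcript_fc,
                 "protein_fc": e.protein_fc, "direction": e.direction}
                for fid, e in self.effects.items()]
        return pd.DataFrame(rows, columns=["feature_id", "transcript_fc",
                                           "protein_fc", "direction"])


#: Metabolite response directions in La-grown cells: sugar-phosphate /
#: upper-glycolytic and early-TCA pools drop, TCA-derived amino acids and
#: compatible solutes rise, mid-TCA acids stay flat.
MetabolitePattern = dict[str, str]

DEFAULT_METABOLITE_PATTERN: MetabolitePattern = {
    "sedoheptulose_7p": "down", "fructose_6p": "down", "glucose_6p": "down",
    "pep": "down", "3pg": "down", "citrate": "down", "aconitate": "down",
    "fumarate": "flat", "malate": "flat", "succinate": "flat",
    "glutamate": "up", "glutamine": "up", "asparagine": "up",
    "ectoine": "up", "glycerate": "up", "agmatine": "up",
}


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def simulate_offgas(spec: ConditionSpec, planted_ratio: float,
                    planted_yield: float | None = None,
                    duration_h: float = 24.0, dt_h: float = 0.5,
                    noise_sd_pct: float = 1.0, seed: int = 0) -> pd.DataFrame:
    """Outlet-percentage time series for one steady-state chemostat.

    The planted CH₄ consumption follows from the condition's dilution
    rate and biomass via the planted yield (defaults to the preset for
    ``spec.label``); O₂ consumption is ``planted_ratio`` times that.
    ``noise_sd_pct`` is the analyzer precision as percent of reading
    (multiplicative Gaussian noise on outlet percentages).  Ground truth
    is stored in ``DataFrame.attrs["truth"]``.
    """
    if not 1.0 <= planted_ratio <= 2.0:
        raise ValueError("planted_ratio must lie in [1, 2]")
    if noise_sd_pct < 0:
        raise ValueError("noise_sd_pct must be >= 0")
    if planted_yield is None:
        if spec.label not in PLANTED_PHYSIOLOGY:
            raise ValueError(f"no planted yield known for condition {spec.label!r}")
        planted_yield = PLANTED_PHYSIOLOGY[spec.label][0]

    biomass_g_h = spec.biomass_conc * spec.dilution_rate * spec.culture_volume
    ch4_mmol_h = biomass_g_h / planted_yield / CH4_MOLAR_MASS * 1000.0
    o2_mmol_h = planted_ratio * ch4_mmol_h
    ch4_drop_pct = ch4_mmol_h * MOLAR_VOLUME_L / 1000.0 / spec.gas_flow * 100.0
    o2_drop_pct = o2_mmol_h * MOLAR_VOLUME_L / 1000.0 / spec.gas_flow * 100.0
    ch4_out = spec.inlet_ch4_pct - ch4_drop_pct
    o2_out = spec.inlet_o2_pct - o2_drop_pct
    if ch4_out < 0 or o2_out < 0:
        raise ValueError(
            f"implied outlet percentage negative (CH4 {ch4_out:.2f}%, O2 "
            f"{o2_out:.2f}%): gas supply cannot sustain the planted consumption")
    # CO2 released = CH4 carbon not fixed into biomass (≈0.5 g C per g DCW)
    assimilated = min(1.0, planted_yield * 0.5 / (12.011 / CH4_MOLAR_MASS))
    co2_out = ch4_drop_pct * (1.0 - assimilated)

    rng = np.random.default_rng(seed)
    time = np.arange(0.0, duration_h + dt_h / 2, dt_h)
    n = len(time)
    rel = noise_sd_pct / 100.0
    df = pd.DataFrame({
        "time_h": time,
        "ch4_out_pct": ch4_out * (1.0 + rel * rng.standard_normal(n)),
        "o2_out_pct": o2_out * (1.0 + rel * rng.standard_normal(n)),
        "co2_out_pct": co2_out * (1.0 + rel * rng.standard_normal(n)),
    })
    df.attrs["truth"] = {
        "condition": spec.label, "planted_yield": planted_yield,
        "planted_ratio": planted_ratio, "ch4_mmol_h": ch4_mmol_h,
        "o2_mmol_h": o2_mmol_h, "seed": seed,
    }
    return df


def _registry_means(n_features: int, registry: EffectRegistry, depth: float,
                    rng: np.random.Generator, which: str
                    ) -> tuple[list[str], np.ndarray, np.ndarray]:
    named = list(registry.effects)
    if n_features < len(named):
        raise ValueError(
            f"n_features={n_features} smaller than registry ({len(named)} entries)")
    ids = named + [f"gene_{i:04d}" for i in range(n_features - len(named))]
    # background means log-uniform over ~4 decades (transcriptome-like
    # dynamic range; this is what makes replicate log-log correlation high)
    base = np.empty(n_features)
    base[:len(named)] = depth
    base[len(named):] = 10 ** rng.uniform(np.log10(depth / 50),
                                          np.log10(depth * 200),
                                          n_features - len(named))
    fc = np.array([getattr(registry, which)(f) for f in ids])
    return ids, base, base * fc


def simulate_counts(n_features: int = 2000,
                    registry: EffectRegistry | None = None,
                    reps_per_condition: int = 2, depth: float = 300.0,
                    dispersion: float = 0.05, seed: int = 0) -> pd.DataFrame:
    """Negative-binomial RNA-seq count table (features × replicates).

    Columns are ``ca_1..ca_r, la_1..la_r``; Ca means are drawn
    log-uniformly around ``depth`` and La means are Ca means times the
    registry transcript fold-change (registry features occupy the first
    rows at their registered ids).  ``dispersion`` is the NB overdispersion
    (variance = μ + d·μ²); 0 reduces to Poisson.  Ground truth sits in
    ``attrs["truth"]``.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    registry = registry if registry is not None else EffectRegistry()
    rng = np.random.default_rng(seed)
    ids, mu_ca, mu_la = _registry_means(n_features, registry, depth, rng,
                                        "transcript_fc")
    if mu_la.max() > 0 and depth < 50:
        import warnings
        warnings.warn("sequencing depth may be too small to express the "
                      "largest planted effects", stacklevel=2)

    def draw(mu: np.ndarray, reps: int) -> np.ndarray:
        out = np.empty((len(mu), reps))
        for j in range(reps):
            if dispersion == 0:
                out[:, j] = rng.poisson(mu)
            else:
                shape = 1.0 / dispersion
                lam = rng.gamma(shape, mu * dispersion)
                out[:, j] = rng.poisson(lam)
        return out

    data = np.hstack([draw(mu_ca, reps_per_condition),
                      draw(mu_la, reps_per_condition)])
    cols = ([f"ca_{j + 1}" for j in range(reps_per_condition)] +
            [f"la_{j + 1}" for j in range(reps_per_condition)])
    df = pd.DataFrame(data.astype(int), index=pd.Index(ids, name="feature_id"),
                      columns=cols)
    df.attrs["truth"] = registry.to_frame()
    df.attrs["params"] = {"depth": depth, "dispersion": dispersion, "seed": seed}
    return df


def simulate_spectral_counts(n_proteins: int = 500,
                             registry: EffectRegistry | None = None,
                             reps: int = 3, mean_count: float = 30.0,
                             seed: int = 0) -> pd.DataFrame:
    """Poisson spectral-count table (proteins × replicates).

    Registry proteins take the registered protein fold-change (e.g. the
    MxaFI subunits collapse to ~1/20 in La, XoxF roughly doubles).
    """
    if mean_count <= 0:
        raise ValueError("mean_count must be > 0")
    registry = registry if registry is not None else EffectRegistry()
    rng = np.random.default_rng(seed)
    ids, mu_ca, mu_la = _registry_means(n_proteins, registry, mean_count, rng,
                                        "protein_fc")
    data = np.hstack([
        rng.poisson(np.repeat(mu_ca[:, None], reps, axis=1)),
        rng.poisson(np.repeat(mu_la[:, None], reps, axis=1)),
    ])
    cols = ([f"ca_{j + 1}" for j in range(reps)] +
            [f"la_{j + 1}" for j in range(reps)])
    df = pd.DataFrame(data.astype(int), index=pd.Index(ids, name="protein_id"),
                      columns=cols)
    df.attrs["truth"] = registry.to_frame()
    df.attrs["params"] = {"mean_count": mean_count, "seed": seed}
    return df


def simulate_metabolites(pattern: MetabolitePattern | None = None,
                         effect_magnitude_log2: float = 1.0, reps: int = 3,
                         noise_sd: float = 0.25, seed: int = 0) -> pd.DataFrame:
    """Log-normal metabolite abundance table (metabolites × replicates).

    "down" metabolites get −``effect_magnitude_log2`` in La, "up" get
    +, "flat" get 0; ``noise_sd`` is the replicate SD on the log2 scale.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    pattern = pattern if pattern is not None else dict(DEFAULT_METABOLITE_PATTERN)
    bad = {m: d for m, d in pattern.items() if d not in ("up", "down", "flat")}
    if bad:
        raise ValueError(f"unknown directions: {bad}")
    rng = np.random.default_rng(seed)
    ids = list(pattern)
    base_log2 = rng.uniform(6.0, 12.0, len(ids))
    shift = np.array([{"up": 1.0, "down": -1.0, "flat": 0.0}[pattern[m]]
                      for m in ids]) * effect_magnitude_log2
    ca = base_log2[:, None] + noise_sd * rng.standard_normal((len(ids), reps))
    la = (base_log2 + shift)[:, None] + noise_sd * rng.standard_normal((len(ids), reps))
    data = np.power(2.0, np.hstack([ca, la]))
    cols = ([f"ca_{j + 1}" for j in range(reps)] +
            [f"la_{j + 1}" for j in range(reps)])
    df = pd.DataFrame(data, index=pd.Index(ids, name="metabolite"), columns=cols)
    df.attrs["truth"] = pd.DataFrame({
        "metabolite": ids,
        "direction": [pattern[m] for m in ids],
        "planted_log2fc": shift,
    })
    df.attrs["params"] = {"effect_magnitude_log2": effect_magnitude_log2,
                          "noise_sd": noise_sd, "seed": seed}
    return df


def welch_de_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Simple DE table (log2fc + p-value) from a two-condition count table.

    Welch's t-test on log2(count+1) between the ``ca_*`` and ``la_*``
    column groups; a stand-in for a dedicated count-model DE tool so the
    DE-calling rules can be exercised end to end on synthetic data.
    """
    ca_cols = [c for c in counts.columns if c.startswith("ca_")]
    la_cols = [c for c in counts.columns if c.startswith("la_")]
    if not ca_cols or not la_cols:
        raise ValueError("count table must have ca_* and la_* columns")
    log_ca = np.log2(counts[ca_cols].to_numpy(float) + 1.0)
    log_la = np.log2(counts[la_cols].to_numpy(float) + 1.0)
    log2fc = log_la.mean(axis=1) - log_ca.mean(axis=1)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        _, pvals = stats.ttest_ind(log_la, log_ca, axis=1, equal_var=False)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    return pd.DataFrame({
        "feature_id": counts.index,
        "log2fc": log2fc,
        "pvalue": pvals,
    }).reset_index(drop=True)
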