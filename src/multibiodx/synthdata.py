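"""Synthetic two-group cohort generator (SZ patients vs healthy controls).

The clinical data behind this analysis — resting EEG, 16S-derived taxa
abundances and routine blood panels — are not publicly available, so the
package ships a generative stand-in with the statistical structure the
analysis assumes:

* a cohort of ~49 SZ and ~50 HC subjects with age/sex/education covariates;
* 16-channel, 1000 Hz eyes-closed EEG whose band-specific inter-channel
  phase coupling differs by group, giving direct control over the
  phase-locking values measured downstream;
* a subjects x 171 taxa abundance table with zero-inflation tuned so the
  downstream prevalence filter retains ~77 taxa, and group log-fold-changes
  on named genera;
* a 12-feature blood panel (5 cell counts, 4 inflammation indices derived
  from them, 3 serum markers) with group mean shifts.

All distributional choices are explicit, configurable stand-ins — no
empirical distributional information is available for any modality.  Every
generator
is deterministic for a fixed seed; randomness flows from one root seed
through named substreams (cohort / eeg / taxa / blood) so each modality
can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .eeg_preprocess import DEFAULT_BANDS, SUBBANDS, EEGRecording
from .feature_assembly import blood_indices

__all__ = [
    "CHANNELS_1020",
    "EEGSimParams",
    "BandCoupling",
    "MicrobiotaSimParams",
    "BloodSimParams",
    "make_cohort",
    "simulate_eeg",
    "simulate_microbiota",
    "simulate_blood",
    "simulate_eeg_summary_features",
]

#: The 16 scalp electrodes of the international 10/20 montage used here.
CHANNELS_1020: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4",
    "O1", "O2", "F7", "F8", "T3", "T4", "T5", "T6",
)

_STREAMS = {"cohort": 11, "eeg": 23, "taxa": 37, "blood": 53, "eegfeat": 71}


def _rng(seed: int, stream: str, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), _STREAMS[stream], extra])


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def make_cohort(
    n_sz: int,
    n_hc: int,
    seed: int = 0,
    age_mean: float = 42.0,
    age_sd: float = 13.0,
    male_prob: float = 0.475,
    edu_mean_hc: float = 14.2,
    edu_sd_hc: float = 3.6,
    edu_mean_sz: float = 11.6,
    edu_sd_sz: float = 3.4,
) -> pd.DataFrame:
    """Demographics table for a two-group cohort.

    Ages are drawn from the same normal for both groups (truncated positive);
    education is lower in SZ, mirroring the typical clinical pattern.  The
    demographics are cosmetic covariates — no downstream stage conditions on
    them — but they make the cohort manifest realistic.

    Returns a DataFrame indexed by unique subject_id with columns
    group ('SZ'/'HC'), age, sex ('M'/'F'), education.
    """
    if n_sz < 1 or n_hc < 1:
        raise ValueError("both group sizes must be at least 1")
    rng = _rng(seed, "cohort")
    rows = []
    for group, n, emu, esd in (("SZ", n_sz, edu_mean_sz, edu_sd_sz),
                               ("HC", n_hc, edu_mean_hc, edu_sd_hc)):
        for i in range(n):
            age = _positive_normal(rng, age_mean, age_sd)
            edu = max(0.0, rng.normal(emu, esd))
            sex = "M" if rng.random() < male_prob else "F"
            rows.append((f"{group}{i + 1:03d}", group, age, sex, edu))
    df = pd.DataFrame(rows, columns=["subject_id", "group", "age", "sex", "education"])
    return df.set_index("subject_id")


def _positive_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x > 0:
            return x
    raise RuntimeError("could not draw a positive value")


# ---------------------------------------------------------------------------
# EEG
# ---------------------------------------------------------------------------

@dataclass
class BandCoupling:
    """Phase-coupling configuration of one frequency band.

    strength : baseline coupling in [0, 1] — the amplitude fraction of a
        band oscillator shared by all channels in ``channels`` (1 means the
        coupled channels carry an identical phase, so PLV -> 1).
    channels : the coupled channel set.
    sz_delta : additive change of ``strength`` for SZ subjects.
    """

    strength: float
    channels: tuple[str, ...] = CHANNELS_1020
    sz_delta: float = 0.0

    def effective(self, is_sz: bool) -> float:
        return float(np.clip(self.strength + (self.sz_delta if is_sz else 0.0), 0.0, 1.0))


def default_band_coupling() -> dict[str, BandCoupling]:
    """Baseline coupling 0.35 in every subband; SZ shows reduced theta and
    alpha2 coupling over temporo-parietal channels and a mild beta2 increase —
    qualitatively matching the band/region pattern of reported SZ
    resting-state network alterations."""
    temporal = ("T3", "T4", "T5", "T6", "P3", "P4")
    cfg = {b: BandCoupling(strength=0.35) for b in SUBBANDS}
    cfg["theta"] = BandCoupling(strength=0.45, channels=temporal, sz_delta=-0.20)
    cfg["alpha2"] = BandCoupling(strength=0.45, channels=("P3", "P4", "O1", "O2", "T5", "T6"), sz_delta=-0.15)
    cfg["beta2"] = BandCoupling(strength=0.30, sz_delta=+0.10)
    return cfg


@dataclass
class EEGSimParams:
    """Parameters of the resting-EEG generator.

    Each band contributes, per channel, an amplitude mixture of a shared
    band oscillator (common phase across the coupled set, slow phase jitter)
    and a channel-private oscillator at a random frequency within the band.
    The mixing weight sqrt(coupling) versus sqrt(1-coupling) makes
    band-specific PLV rise monotonically with the configured coupling,
    which is exactly the quantity the downstream pipeline measures.
    No volume conduction or electrode forward model is simulated.
    """

    n_channels: int = 16
    fs: float = 1000.0
    duration: float = 180.0
    band_coupling: dict[str, BandCoupling] = field(default_factory=default_band_coupling)
    band_amplitude: dict[str, float] = field(
        default_factory=lambda: {
            "delta": 1.2, "theta": 1.0, "alpha1": 1.5, "alpha2": 1.3,
            "beta1": 0.7, "beta2": 0.5, "gamma": 0.35,
        }
    )
    noise_sd: float = 0.5
    phase_jitter_sd: float = 0.8       # radians, stationary
    jitter_bandwidth_hz: float = 0.8   # low-pass cutoff of the phase jitter

    def validate(self) -> None:
        if self.n_channels < 1 or self.n_channels > len(CHANNELS_1020):
            raise ValueError("n_channels must be in 1..16")
        top = max(hi for _, hi in DEFAULT_BANDS.values())
        if self.fs <= 2 * top:
            raise ValueError("fs must exceed twice the highest band edge")
        for b, bc in self.band_coupling.items():
            if not 0 <= bc.strength <= 1:
                raise ValueError(f"coupling strength of {b!r} outside [0, 1]")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


def _phase_jitter(rng: np.random.Generator, n: int, fs: float, bw: float, sd: float) -> np.ndarray:
    """Stationary slow phase jitter: low-passed white noise scaled to sd."""
    white = rng.standard_normal(n + int(fs))
    sos = sps.butter(2, bw, btype="low", fs=fs, output="sos")
    x = sps.sosfilt(sos, white)[int(fs):]
    s = x.std()
    return x * (sd / s) if s > 0 else x


def simulate_eeg(
    cohort: pd.DataFrame,
    params: EEGSimParams | None = None,
    seed: int = 0,
    min_epoch_length: float = 2.0,
) -> dict[str, EEGRecording]:
    """Simulate one eyes-closed resting recording per cohort subject."""
    params = params or EEGSimParams()
    params.validate()
    if params.duration < min_epoch_length:
        raise ValueError("duration shorter than one epoch")
    n = int(round(params.fs * params.duration))
    t = np.arange(n) / params.fs
    channels = list(CHANNELS_1020[: params.n_channels])
    out: dict[str, EEGRecording] = {}
    for si, (sid, row) in enumerate(cohort.iterrows()):
        rng = _rng(seed, "eeg", si)
        is_sz = row["group"] == "SZ"
        data = params.noise_sd * rng.standard_normal((params.n_channels, n))
        for band in SUBBANDS:
            lo, hi = DEFAULT_BANDS[band]
            amp = params.band_amplitude.get(band, 1.0)
            bc = params.band_coupling.get(band, BandCoupling(strength=0.0))
            c = bc.effective(is_sz)
            f_shared = rng.uniform(lo + 0.2 * (hi - lo), hi - 0.2 * (hi - lo))
            shared_jit = _phase_jitter(rng, n, params.fs, params.jitter_bandwidth_hz,
                                       params.phase_jitter_sd)
            shared_phase = 2 * np.pi * f_shared * t + shared_jit + rng.uniform(0, 2 * np.pi)
            coupled = set(bc.channels)
            # channel-private frequencies on a shuffled grid spanning the band:
            # guarantees separation, so uncoupled pairs drift apart in phase
            slots = rng.permutation(params.n_channels)
            width = hi - lo
            for ci, ch in enumerate(channels):
                f_own = lo + width * (0.1 + 0.8 * (slots[ci] + 0.5) / params.n_channels)
                own_jit = _phase_jitter(rng, n, params.fs, params.jitter_bandwidth_hz,
                                        params.phase_jitter_sd)
                own_phase = 2 * np.pi * f_own * t + own_jit + rng.uniform(0, 2 * np.pi)
                w = c if ch in coupled else 0.0
                data[ci] += amp * (
                    np.sqrt(w) * np.cos(shared_phase) + np.sqrt(1 - w) * np.cos(own_phase)
                )
        out[sid] = EEGRecording(data=data, fs=params.fs, channel_names=channels)
    return out


# ---------------------------------------------------------------------------
# microbiota
# ---------------------------------------------------------------------------

#: Genus names used for the high-prevalence ("core") taxa, led by the taxa the
#: analysis treats as group-discriminative.
_CORE_GENERA = (
    "Lactobacillus", "Haemophilus", "Prevotella", "Collinsella", "Megamonas",
    "Clostridium", "Anaerostipes", "Dialister", "Slackia", "Odoribacter",
    "Ruminococcus", "Gemmiger", "Bacteroides", "Faecalibacterium", "Roseburia",
    "Blautia", "Bifidobacterium", "Streptococcus", "Akkermansia", "Veillonella",
    "Coprococcus", "Dorea", "Parabacteroides", "Alistipes", "Oscillospira",
    "Sutterella", "Phascolarctobacterium", "Eubacterium", "Fusobacterium",
    "Desulfovibrio",
)


def default_effect_taxa() -> dict[str, float]:
    """Group log-fold-changes (SZ relative to HC) on named core genera.

    Magnitudes are calibrated so a linear classifier on the filtered taxa
    table alone reaches ~70% hold-out accuracy at the reference cohort size —
    the weakest of the three modalities, as reported for gut-microbiota
    features.  Skew and zero-inflation of the abundances make the effective
    discriminability much lower than the log-fold-changes suggest.
    """
    return {
        "Lactobacillus": 1.8,
        "Haemophilus": 1.4,
        "Prevotella": -1.4,
        "Collinsella": 1.0,
        "Megamonas": 1.2,
        "Clostridium": 1.0,
    }


@dataclass
class MicrobiotaSimParams:
    """Zero-inflated log-normal taxa abundances.

    ``n_core`` taxa have presence probability ``core_prevalence`` (they
    survive the downstream more-than-85%-missing filter) and the remaining
    ``n_taxa - n_core`` are rare with ``rare_prevalence`` (they are removed).
    A taxon absent in a subject has abundance exactly zero; present taxa are
    log-normal, with SZ group shifts (log-fold-changes) on ``effect_taxa``.
    """

    n_taxa: int = 171
    n_core: int = 77
    core_prevalence: float = 0.90
    rare_prevalence: float = 0.05
    abundance_logmean: float = 2.0
    abundance_logsd: float = 1.0
    effect_taxa: dict[str, float] = field(default_factory=default_effect_taxa)

    def validate(self) -> None:
        if self.n_taxa < 1:
            raise ValueError("n_taxa must be at least 1")
        if not (0 <= self.n_core <= self.n_taxa):
            raise ValueError("n_core must be in [0, n_taxa]")
        for p in (self.core_prevalence, self.rare_prevalence):
            if not 0 <= p <= 1:
                raise ValueError("prevalence must be in [0, 1]")

    def taxon_names(self) -> list[str]:
        names = list(_CORE_GENERA[: min(self.n_core, len(_CORE_GENERA))])
        i = 1
        while len(names) < self.n_core:
            names.append(f"CoreTaxon_{i:03d}")
            i += 1
        names += [f"RareTaxon_{i:03d}" for i in range(1, self.n_taxa - self.n_core + 1)]
        return names

    def prevalences(self) -> np.ndarray:
        p = np.full(self.n_taxa, self.rare_prevalence)
        p[: self.n_core] = self.core_prevalence
        return p


def simulate_microbiota(
    cohort: pd.DataFrame,
    params: MicrobiotaSimParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Subjects x taxa abundance table with zero-inflation and group effects.

    Zeros encode absence (the reading of "missing" used by the prevalence
    filter).  Abundances are in arbitrary units; the analysis consumes them
    directly as features, so no compositional normalisation is applied.
    """
    params = params or MicrobiotaSimParams()
    params.validate()
    rng = _rng(seed, "taxa")
    names = params.taxon_names()
    prev = params.prevalences()
    n_sub = len(cohort)
    present = rng.random((n_sub, params.n_taxa)) < prev
    logmu = np.full(params.n_taxa, params.abundance_logmean)
    lfc = np.array([params.effect_taxa.get(nm, 0.0) for nm in names])
    is_sz = (cohort["group"] == "SZ").to_numpy()[:, None]
    mu = logmu[None, :] + lfc[None, :] * is_sz
    abund = np.exp(rng.normal(mu, params.abundance_logsd))
    abund[~present] = 0.0
    return pd.DataFrame(abund, index=cohort.index, columns=names)


# ---------------------------------------------------------------------------
# blood
# ---------------------------------------------------------------------------

BLOOD_FEATURES: tuple[str, ...] = (
    "WBC", "NEU", "LYM", "PLT", "MON",          # cell counts
    "NLR", "PLR", "MLR", "SIII",                # derived indices
    "SOD", "HCY", "CRP",                        # serum markers
)


def default_blood_params() -> dict[str, tuple[float, float, float]]:
    """Per-feature (HC mean, SZ mean, SD) for counts and serum markers.

    Counts are in 10^9 cells/L (PLT likewise), SOD in U/mL, homocysteine
    (HCY) in umol/L, CRP in mg/L.  Directions mirror the inflammation /
    oxidative-stress literature on chronic SZ: higher WBC/NEU/MON/CRP/HCY,
    lower SOD, slightly lower LYM.
    """
    return {
        "WBC": (6.1, 6.8, 1.5),
        "NEU": (3.5, 4.2, 1.1),
        "LYM": (2.1, 1.9, 0.55),
        "PLT": (245.0, 255.0, 55.0),
        "MON": (0.42, 0.50, 0.13),
        "SOD": (165.0, 142.0, 24.0),
        "HCY": (11.5, 15.5, 4.0),
        "CRP": (1.6, 2.6, 1.3),
    }


@dataclass
class BloodSimParams:
    """Group means and SDs of the 8 directly-measured blood features.

    The 4 inflammation indices (NLR, PLR, MLR, SIII) are never drawn — they
    are recomputed from the simulated counts, so the table is internally
    consistent by construction.  Non-positive draws of counts are resampled
    (lymphocytes in particular must stay positive for the ratios).
    """

    features: dict[str, tuple[float, float, float]] = field(default_factory=default_blood_params)

    def validate(self) -> None:
        required = {"WBC", "NEU", "LYM", "PLT", "MON", "SOD", "HCY", "CRP"}
        missing = required - set(self.features)
        if missing:
            raise ValueError(f"missing blood feature parameters: {sorted(missing)}")


def simulate_blood(
    cohort: pd.DataFrame,
    params: BloodSimParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Subjects x 12 blood features, with ratio columns derived from counts."""
    params = params or BloodSimParams()
    params.validate()
    rng = _rng(seed, "blood")
    cols: dict[str, np.ndarray] = {}
    is_sz = (cohort["group"] == "SZ").to_numpy()
    for name, (mu_hc, mu_sz, sd) in params.features.items():
        mu = np.where(is_sz, mu_sz, mu_hc)
        draws = rng.normal(mu, sd)
        for _ in range(1000):
            bad = draws <= 0
            if not bad.any():
                break
            draws[bad] = rng.normal(mu[bad], sd)
        draws = np.maximum(draws, 1e-3)
        cols[name] = draws
    nlr, plr, mlr, siii = blood_indices(
        cols["WBC"], cols["NEU"], cols["LYM"], cols["PLT"], cols["MON"]
    )
    cols.update({"NLR": nlr, "PLR": plr, "MLR": mlr, "SIII": siii})
    return pd.DataFrame({c: cols[c] for c in BLOOD_FEATURES}, index=cohort.index)


# ---------------------------------------------------------------------------
# reduced EEG-feature generator for classification-stage experiments
# ---------------------------------------------------------------------------

def simulate_eeg_summary_features(
    cohort: pd.DataFrame,
    n_features: int = 60,
    n_informative: int = 10,
    effect_size: float = 0.85,
    seed: int = 0,
) -> pd.DataFrame:
    """Directly simulate network-AUC-style EEG features.

    A reduced generator for experiments on the classification stage that
    need many cohort replicates: instead of running the full
    signal -> PLV -> graph -> AUC chain, it draws standardized Gaussian
    features with a group mean shift of ``effect_size`` SD on the first
    ``n_informative`` features.  The default shift is calibrated so a linear
    classifier on these features alone reaches ~78% hold-out accuracy at the
    reference cohort size, the middle of the single-modality operating range.
    Feature names mimic the band_attr_channel convention.  Use the full chain (``simulate_eeg`` + preprocessing +
    ``eeg_feature_vector``) whenever the network stage itself is under test.
    """
    if n_features < 1 or not 0 <= n_informative <= n_features:
        raise ValueError("invalid feature counts")
    rng = _rng(seed, "eegfeat")
    is_sz = (cohort["group"] == "SZ").to_numpy()[:, None]
    x = rng.standard_normal((len(cohort), n_features))
    x[:, :n_informative] += effect_size * is_sz
    bands = list(SUBBANDS) + ["whole"]
    names = [
        f"{bands[i % len(bands)]}_aNe_{CHANNELS_1020[i % 16]}_{i:03d}"
        for i in range(n_features)
    ]
    return pd.DataFrame(x, index=cohort.index, columns=names)
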