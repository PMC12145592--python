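"""Synthetic NIR data: band libraries, instrument profiles, fermentation kinetics.

The simulator emulates the study conditions of a 2,3-butanediol (2,3-BDO)
fermentation monitoring campaign with *Zymomonas mobilis*:

* **Pure-component band library** — each constituent absorbs as a sum of
  Gaussian bands (Beer-Lambert).  Bands live in the C-H 1st-overtone region
  (~6200-5600 cm^-1) and the much stronger combination region
  (~4800-4000 cm^-1); per constituent the summed combination-region amplitude
  is 10x the summed overtone amplitude, and the diol/ketol products absorb
  more strongly per g/L than the sugars.  Band centers and widths are
  package defaults chosen for plausibility, not measured coefficients.
* **Instrument profiles** — a lab-grade FT spectrometer used at-line
  (12,003-3772 cm^-1, 8 cm^-1, 0.2 mm pathlength) and on-line through a fiber
  probe (9503-4000 cm^-1, 2 mm pathlength, fiber attenuation, saturation of
  the strong water bands), plus a low-cost MEMS spectrometer
  (2000-2450 nm, 1 nm, ~4.8x the channel noise of the lab instrument).
* **Kinetics** — a discrete-time model of glucose/xylose co-consumption with
  glucose preference, a Markov dissolved-oxygen (DO) state, and DO-dependent
  product allocation: optimal DO makes 2,3-BDO, DO-deficient steps make
  irreversible glycerol, DO-excess steps make the intermediate acetoin, which
  is later reduced to 2,3-BDO when DO recovers.

All stochastic operations take a ``seed`` (int or ``numpy.random.Generator``)
and are reproducible.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DesignFailureError,
    LibraryMismatchError,
    ParameterError,
    SampleSizeError,
)
from .spectra import (
    CONSTITUENTS,
    CONTAMINANTS,
    WAVELENGTH,
    WAVENUMBER,
    ConcentrationTable,
    SpectralAxis,
    SpectraSet,
)

#: cm^-1 windows used to state the library's qualitative region constraints.
OVERTONE_REGION = (5600.0, 6200.0)
COMBINATION_REGION = (4000.0, 4800.0)

DO_STATES = ("low", "optimal", "high")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass(frozen=True)
class BandDefinition:
    """One Gaussian absorption band.

    ``amplitude`` is in absorbance units per (g/L) per mm pathlength for
    constituents, and per mm (fixed matrix) for the water background.
    """

    center: float  # cm^-1
    width: float   # Gaussian sigma, cm^-1
    amplitude: float

    def __post_init__(self):
        if self.width <= 0:
            raise ParameterError("band width must be > 0")


@dataclass(frozen=True)
class PureComponentLibrary:
    """Per-constituent band sets; ``water`` holds the solvent background."""

    bands: Mapping[str, tuple[BandDefinition, ...]]

    def __post_init__(self):
        if "water" not in self.bands:
            raise ParameterError("library must include a 'water' background entry")

    def constituents(self) -> list[str]:
        return [k for k in self.bands if k != "water"]

    def render_component(self, name: str, nu: np.ndarray) -> np.ndarray:
        """Absorptivity spectrum of one component on the cm^-1 grid ``nu``."""
        if name not in self.bands:
            raise LibraryMismatchError(f"constituent {name!r} is not in the library")
        out = np.zeros_like(nu, dtype=float)
        for b in self.bands[name]:
            out += b.amplitude * np.exp(-0.5 * ((nu - b.center) / b.width) ** 2)
        return out


def build_default_library() -> PureComponentLibrary:
    """Default band library for the five constituents plus water.

    Encodes the qualitative facts the simulator must reproduce: every
    constituent has bands in both NIR regions, combination-region amplitude
    sums to exactly 10x the 1st-overtone sum, the products 2,3-BDO and
    acetoin absorb more strongly per g/L than the sugars, and no two
    constituents share a band set.  The numeric centers/widths are invented
    package defaults (no published extinction coefficients exist) and are
    fully overridable by constructing a custom library.
    """
    return PureComponentLibrary(
        bands={
            "glucose": (
                BandDefinition(4400.0, 45.0, 0.006),
                BandDefinition(4290.0, 60.0, 0.004),
                BandDefinition(5920.0, 40.0, 0.0006),
                BandDefinition(5780.0, 50.0, 0.0004),
            ),
            "xylose": (
                BandDefinition(4420.0, 50.0, 0.005),
                BandDefinition(4250.0, 55.0, 0.005),
                BandDefinition(5940.0, 45.0, 0.0005),
                BandDefinition(5800.0, 55.0, 0.0005),
            ),
            "bdo_total": (
                BandDefinition(4350.0, 40.0, 0.015),
                BandDefinition(4700.0, 70.0, 0.010),
                BandDefinition(5870.0, 35.0, 0.0015),
                BandDefinition(6050.0, 60.0, 0.0010),
            ),
            "acetoin": (
                BandDefinition(4450.0, 45.0, 0.014),
                BandDefinition(4650.0, 60.0, 0.008),
                BandDefinition(5890.0, 40.0, 0.0012),
                BandDefinition(6100.0, 50.0, 0.0010),
            ),
            "glycerol": (
                BandDefinition(4500.0, 55.0, 0.008),
                BandDefinition(4330.0, 45.0, 0.006),
                BandDefinition(5820.0, 45.0, 0.0008),
                BandDefinition(6000.0, 55.0, 0.0006),
            ),
            # Water background, absorbance per mm: the strong combination band
            # near 5150 cm^-1, the O-H fundamental tail below ~4300 cm^-1 and a
            # weaker 1st-overtone band near 6900 cm^-1.  At a 2 mm pathlength
            # (plus fiber loss) the first two push past the detector ceiling,
            # producing the on-line saturation regions.
            "water": (
                BandDefinition(5150.0, 200.0, 9.0),
                BandDefinition(3900.0, 250.0, 8.0),
                BandDefinition(6900.0, 250.0, 1.0),
            ),
        }
    )


@dataclass(frozen=True)
class InstrumentProfile:
    """Everything the renderer needs to emulate one instrument/modality."""

    name: str
    axis: SpectralAxis
    pathlength_mm: float
    noise_sd: float
    attenuation: float = 1.0          # multiplicative transmittance loss (fiber), (0, 1]
    saturation_limit: float = 3.0     # absorbance ceiling (hard clip)
    scatter_sd_mult: float = 0.0      # sd of the per-sample multiplicative scatter factor
    scatter_sd_add: float = 0.0       # sd of the per-sample additive offset
    rail_noise_sd: float | None = None  # instability of saturated channels; None -> derived
    instrument: str = "lab_grade"
    modality: str = "at_line"

    def __post_init__(self):
        if self.pathlength_mm <= 0:
            raise ParameterError("pathlength_mm must be > 0")
        if self.noise_sd < 0 or self.scatter_sd_mult < 0 or self.scatter_sd_add < 0:
            raise ParameterError("noise/scatter scales must be >= 0")
        if not (0 < self.attenuation <= 1):
            raise ParameterError("attenuation must be in (0, 1]")
        if self.saturation_limit <= 0:
            raise ParameterError("saturation_limit must be > 0")

    def effective_rail_noise_sd(self) -> float:
        """Instability of absorbance readings at the saturation rail.

        Additive channel noise reflects roughly constant detector intensity
        noise, and absorbance noise grows as 10^A; a channel railed at the
        ceiling therefore wobbles by about ``noise_sd * 10^(limit - 1)``
        (the working range of the unsaturated spectrum being ~1 AU).
        Override with an explicit ``rail_noise_sd``.
        """
        if self.rail_noise_sd is not None:
            return self.rail_noise_sd
        if not np.isfinite(self.saturation_limit):
            return 0.0
        return self.noise_sd * 10.0 ** (self.saturation_limit - 1.0)

    def noiseless(self) -> "InstrumentProfile":
        """Copy with all stochastic terms, attenuation and clipping disabled."""
        return dataclasses.replace(
            self,
            noise_sd=0.0,
            scatter_sd_mult=0.0,
            scatter_sd_add=0.0,
            rail_noise_sd=0.0,
            attenuation=1.0,
            saturation_limit=np.inf,
        )


#: Baseline additive channel noise of the lab-grade FT instrument (AU).
LAB_NOISE_SD = 5e-4
#: Measured low-cost/lab-grade noise ratio encoded into the default profiles.
LOW_COST_NOISE_RATIO = 4.8


def default_profiles() -> dict[str, InstrumentProfile]:
    """The three study configurations.

    Fiber attenuation and the absorbance ceiling are not published; the
    defaults (50% transmittance, 3.0 AU) are invented, tunable values chosen
    so that at 2 mm the strong water bands saturate while the analyte windows
    stay on scale.
    """
    return {
        "lab_at_line": InstrumentProfile(
            name="lab_at_line",
            axis=SpectralAxis(np.arange(3772.0, 12004.0, 8.0), WAVENUMBER),
            pathlength_mm=0.2,
            noise_sd=LAB_NOISE_SD,
            scatter_sd_mult=0.001,
            scatter_sd_add=0.002,
            instrument="lab_grade",
            modality="at_line",
        ),
        "low_cost_at_line": InstrumentProfile(
            name="low_cost_at_line",
            axis=SpectralAxis(np.arange(2000.0, 2451.0, 1.0), WAVELENGTH),
            pathlength_mm=0.2,
            noise_sd=LAB_NOISE_SD * LOW_COST_NOISE_RATIO,
            scatter_sd_mult=0.001,
            scatter_sd_add=0.002,
            instrument="low_cost",
            modality="at_line",
        ),
        "lab_on_line": InstrumentProfile(
            name="lab_on_line",
            axis=SpectralAxis(np.arange(4000.0, 9504.0, 8.0), WAVENUMBER),
            pathlength_mm=2.0,
            noise_sd=LAB_NOISE_SD,
            attenuation=0.5,
            scatter_sd_mult=0.03,
            scatter_sd_add=0.01,
            instrument="lab_grade",
            modality="on_line",
        ),
    }


def get_profile(name_or_profile) -> InstrumentProfile:
    if isinstance(name_or_profile, InstrumentProfile):
        return name_or_profile
    profiles = default_profiles()
    if name_or_profile not in profiles:
        raise ParameterError(f"unknown instrument profile {name_or_profile!r}")
    return profiles[name_or_profile]


# ---------------------------------------------------------------------------
# concentration designs
# ---------------------------------------------------------------------------

def simulate_feasibility_design(
    n: int = 40,
    c_max: float = 60.0,
    seed=0,
    max_abs_corr: float = 0.3,
    max_tries: int = 1000,
) -> ConcentrationTable:
    """Uncorrelated random mixture design for the feasibility study.

    Draws ``n`` samples of the five constituents uniformly on [0, c_max] and
    rejection-resamples the whole design until every pairwise Pearson
    correlation satisfies |r| <= ``max_abs_corr``.
    """
    if n < 5:
        raise ParameterError("feasibility design needs n >= 5")
    if c_max <= 0:
        raise ParameterError("c_max must be > 0")
    if not (0 < max_abs_corr < 1):
        raise ParameterError("max_abs_corr must be in (0, 1)")
    rng = _rng(seed)
    for _ in range(max_tries):
        design = rng.uniform(0.0, c_max, size=(n, len(CONSTITUENTS)))
        corr = np.corrcoef(design, rowvar=False)
        off = corr[np.triu_indices(len(CONSTITUENTS), k=1)]
        if np.all(np.abs(off) <= max_abs_corr):
            df = pd.DataFrame(design, columns=CONSTITUENTS)
            df.insert(0, "sample_id", [f"F{i:03d}" for i in range(n)])
            df["experiment_id"] = "FEAS"
            return ConcentrationTable(df)
    raise DesignFailureError(
        f"could not satisfy |r| <= {max_abs_corr} in {max_tries} resamples"
    )


def _default_yields() -> dict[str, tuple[float, float, float]]:
    # (bdo, acetoin, glycerol) mass yields per g sugar consumed, by DO state.
    return {
        "optimal": (0.45, 0.06, 0.00),
        "low": (0.25, 0.02, 0.30),
        "high": (0.15, 0.40, 0.00),
    }


def _default_transition() -> dict[str, dict[str, float]]:
    return {
        "optimal": {"low": 0.05, "optimal": 0.90, "high": 0.05},
        "low": {"low": 0.70, "optimal": 0.30, "high": 0.00},
        "high": {"low": 0.00, "optimal": 0.30, "high": 0.70},
    }


@dataclass
class KineticsParams:
    """Discrete-time fermentation kinetics.

    Units: concentrations g/L, rates g/L/h, times h.  ``xylose_repression``
    is the factor applied to the xylose uptake rate while glucose remains
    above ``g_min`` (glucose is consumed preferentially).  Product yields are
    state-dependent mass fractions of consumed sugar; within each DO state
    they must sum to <= 1.  ``acetoin_conversion`` is the fraction of the
    acetoin pool reduced to 2,3-BDO per step outside DO-excess conditions.
    """

    glucose_0: float = 80.0
    xylose_0: float = 40.0
    r_glucose: float = 6.0
    r_xylose: float = 2.5
    xylose_repression: float = 0.2
    g_min: float = 1.0
    yields: dict = field(default_factory=_default_yields)
    do_transition: dict = field(default_factory=_default_transition)
    do_initial: str = "optimal"
    do_fixed: str | None = None
    acetoin_conversion: float = 0.15
    feed_rate: float = 0.0
    feed_start_h: float = 0.0
    duration_h: float = 48.0
    step_h: float = 1.0

    def __post_init__(self):
        for name in ("glucose_0", "xylose_0", "r_glucose", "r_xylose", "feed_rate"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if not (0 <= self.xylose_repression <= 1):
            raise ParameterError("xylose_repression must be in [0, 1]")
        if not (0 <= self.acetoin_conversion < 1):
            raise ParameterError("acetoin_conversion must be in [0, 1)")
        if self.step_h <= 0 or self.duration_h <= 0:
            raise ParameterError("step_h and duration_h must be > 0")
        for state in DO_STATES:
            y = self.yields[state]
            if any(v < 0 for v in y) or sum(y) > 1 + 1e-12:
                raise ParameterError(f"yields in state {state!r} must be >= 0 and sum <= 1")
        if self.do_fixed is not None and self.do_fixed not in DO_STATES:
            raise ParameterError(f"do_fixed must be one of {DO_STATES}")


def simulate_fermentation_timecourse(
    params: KineticsParams, seed=0, id_prefix: str = "T"
) -> ConcentrationTable:
    """Simulate one fermentation trajectory sampled every ``step_h`` hours.

    Guarantees, by construction: 2,3-BDO and glycerol are non-decreasing
    (irreversible end products); acetoin may rise under DO excess and fall as
    it is reduced back to 2,3-BDO; all concentrations stay >= 0; the total
    product mass formed never exceeds the state-wise yield-weighted sugar
    consumption.  Extra columns ``time_h``, ``do_state`` and cumulative
    ``sugar_consumed`` are emitted for diagnostics.
    """
    rng = _rng(seed)
    g, x = params.glucose_0, params.xylose_0
    bdo = ace = gly = 0.0
    consumed = 0.0
    state = params.do_fixed or params.do_initial
    times = np.arange(0.0, params.duration_h + 0.5 * params.step_h, params.step_h)
    rows = []
    for t in times:
        rows.append((t, g, x, bdo, ace, gly, state, consumed))
        if params.feed_rate > 0 and t >= params.feed_start_h:
            g += params.feed_rate * params.step_h
        dg = min(g, params.r_glucose * params.step_h)
        rx = params.r_xylose * (params.xylose_repression if g > params.g_min else 1.0)
        dx = min(x, rx * params.step_h)
        g -= dg
        x -= dx
        ds = dg + dx
        consumed += ds
        yb, ya, yg = params.yields[state]
        bdo += yb * ds
        ace += ya * ds
        gly += yg * ds
        if state != "high":
            conv = params.acetoin_conversion * ace
            ace -= conv
            bdo += conv
        if params.do_fixed is None:
            probs = params.do_transition[state]
            state = rng.choice(DO_STATES, p=[probs.get(s, 0.0) for s in DO_STATES])
        else:
            state = params.do_fixed
    df = pd.DataFrame(
        rows,
        columns=["time_h", "glucose", "xylose", "bdo_total", "acetoin", "glycerol",
                 "do_state", "sugar_consumed"],
    )
    df.insert(0, "sample_id", [f"{id_prefix}{i:03d}" for i in range(len(df))])
    return ConcentrationTable(df)


# ---------------------------------------------------------------------------
# spectral rendering
# ---------------------------------------------------------------------------

def render_spectra(
    conc: ConcentrationTable,
    lib: PureComponentLibrary,
    prof: InstrumentProfile,
    seed=0,
) -> SpectraSet:
    """Render absorbance spectra for a concentration table (Beer-Lambert).

    Per sample: noiseless absorbance
    ``A0(nu) = pathlength * (sum_i c_i * lib_i(nu) + water(nu))``; then the
    per-sample affine scatter ``a * A0 + b`` with ``a ~ N(1, scatter_sd_mult)``
    and ``b ~ N(0, scatter_sd_add)``; then fiber attenuation
    ``A += -log10(attenuation)``; then additive channel noise
    ``N(0, noise_sd)``; then hard clipping at ``saturation_limit``.

    Contaminant columns (ethanol, lactic acid, acetic acid) are not spectrally
    modeled and are ignored here; any modeled constituent with a nonzero
    concentration must be present in the library.
    """
    rng = _rng(seed)
    nu = prof.axis.in_wavenumber()
    n = len(conc)
    modeled = [c for c in conc.data.columns
               if c in CONSTITUENTS or (c not in CONTAMINANTS and c in lib.bands)]
    for c in modeled:
        if c not in lib.bands:
            if np.any(conc.data[c].to_numpy() != 0):
                raise LibraryMismatchError(f"constituent {c!r} has no library entry")
    modeled = [c for c in modeled if c in lib.bands]
    comps = np.stack([lib.render_component(c, nu) for c in modeled])  # k x p
    cmat = conc.data[modeled].to_numpy(dtype=float)                    # n x k
    water = lib.render_component("water", nu)
    a0 = prof.pathlength_mm * (cmat @ comps + water[None, :])
    a_fac = rng.normal(1.0, prof.scatter_sd_mult, size=(n, 1)) if prof.scatter_sd_mult else np.ones((n, 1))
    b_off = rng.normal(0.0, prof.scatter_sd_add, size=(n, 1)) if prof.scatter_sd_add else np.zeros((n, 1))
    a = a_fac * a0 + b_off
    a = a - math.log10(prof.attenuation)
    if prof.noise_sd:
        a = a + rng.normal(0.0, prof.noise_sd, size=a.shape)
    saturated = a >= prof.saturation_limit
    a = np.minimum(a, prof.saturation_limit)
    # A railed detector does not report a clean constant: near-zero light
    # makes the computed absorbance unstable, so saturated channels wobble
    # around the ceiling instead of carrying reproducible values.
    rail_sd = prof.effective_rail_noise_sd()
    if rail_sd > 0 and saturated.any():
        a[saturated] += rng.normal(0.0, rail_sd, size=int(saturated.sum()))

    meta = pd.DataFrame({
        "sample_id": conc.sample_ids,
        "experiment_id": conc.data["experiment_id"] if "experiment_id" in conc.data else "SIM",
        "time_h": conc.data["time_h"] if "time_h" in conc.data else np.nan,
        "instrument": prof.instrument,
        "modality": prof.modality,
        "vessel_volume_L": np.nan,
    })
    return SpectraSet(prof.axis, a, meta)


def simulate_reference_measurement(
    true_conc: ConcentrationTable, base_sd: float = 0.5, seed=0
) -> ConcentrationTable:
    """Emulate HPLC reference measurements: additive Gaussian error, clipped at 0.

    Glucose error scales with the dilution factor ``d = max(1, ceil(c/36))``
    needed to bring the sample into the 6-36 g/L HPLC calibration range, so
    samples above ~80 g/L carry at least 3x the base error.
    """
    if base_sd < 0:
        raise ParameterError("base_sd must be >= 0")
    rng = _rng(seed)
    df = true_conc.data.copy()
    for col in CONSTITUENTS + CONTAMINANTS:
        v = df[col].to_numpy(dtype=float)
        sd = np.full_like(v, float(base_sd))
        if col == "glucose":
            sd = sd * np.maximum(1.0, np.ceil(v / 36.0))
        if base_sd > 0:
            v = np.maximum(0.0, v + rng.normal(0.0, 1.0, size=v.shape) * sd)
        df[col] = v
    return ConcentrationTable(df)


def simulate_water_blanks(prof: InstrumentProfile, n: int = 20, seed=0) -> SpectraSet:
    """Render ``n`` blank (water-only) spectra under the given profile."""
    if n < 2:
        raise SampleSizeError("water-blank analysis needs n >= 2 replicates")
    df = pd.DataFrame({c: np.zeros(n) for c in CONSTITUENTS})
    df.insert(0, "sample_id", [f"W{i:03d}" for i in range(n)])
    df["experiment_id"] = "BLANK"
    return render_spectra(ConcentrationTable(df), build_default_library(), prof, seed=seed)


# ---------------------------------------------------------------------------
# campaign orchestration
# ---------------------------------------------------------------------------

@dataclass
class CampaignConfig:
    """A multi-experiment fermentation scanning campaign."""

    n_experiments: int = 10
    samples_per_experiment: int = 8
    profile: InstrumentProfile | str = "lab_at_line"
    seed: int = 0
    contamination_prob: float = 0.0
    contaminant_magnitude: float = 5.0
    reference_base_sd: float = 0.5
    kinetics: KineticsParams = field(default_factory=KineticsParams)
    library: PureComponentLibrary = field(default_factory=build_default_library)

    def __post_init__(self):
        if self.n_experiments < 1 or self.samples_per_experiment < 1:
            raise ParameterError("campaign counts must be positive")
        if not (0 <= self.contamination_prob <= 1):
            raise ParameterError("contamination_prob must be in [0, 1]")


@dataclass
class CampaignResult:
    spectra: SpectraSet
    true_conc: ConcentrationTable
    measured_conc: ConcentrationTable
    config: CampaignConfig


def simulate_campaign(cfg: CampaignConfig) -> CampaignResult:
    """Simulate a campaign: per-experiment trajectories, rendered and measured.

    Experiment-to-experiment variability is induced by jittering initial sugar
    levels and uptake rates (+-20%).  With probability ``contamination_prob``
    an experiment is contaminated: one random sample gets one contaminant at
    about ``contaminant_magnitude`` g/L, which exercises the 2.5 g/L exclusion
    filter downstream.  Returns spectra, true concentrations, and noisy
    HPLC-like measured concentrations, all keyed by sample/experiment ids.
    """
    prof = get_profile(cfg.profile)
    master = np.random.SeedSequence(cfg.seed)
    exp_seeds = master.spawn(cfg.n_experiments)
    render_rng, ref_rng = (np.random.default_rng(s) for s in master.spawn(2))
    frames = []
    for e, ss in enumerate(exp_seeds):
        rng = np.random.default_rng(ss)
        k = cfg.kinetics
        params = dataclasses.replace(
            k,
            glucose_0=k.glucose_0 * rng.uniform(0.8, 1.2),
            xylose_0=k.xylose_0 * rng.uniform(0.8, 1.2),
            r_glucose=k.r_glucose * rng.uniform(0.8, 1.2),
            r_xylose=k.r_xylose * rng.uniform(0.8, 1.2),
        )
        track = simulate_fermentation_timecourse(params, seed=rng, id_prefix=f"E{e:03d}S")
        df = track.data
        idx = np.unique(np.round(np.linspace(0, len(df) - 1, cfg.samples_per_experiment)).astype(int))
        df = df.iloc[idx].reset_index(drop=True)
        df["experiment_id"] = f"E{e:03d}"
        if cfg.contamination_prob > 0 and rng.uniform() < cfg.contamination_prob:
            j = int(rng.integers(len(df)))
            contaminant = CONTAMINANTS[int(rng.integers(len(CONTAMINANTS)))]
            df.loc[j, contaminant] = cfg.contaminant_magnitude * rng.uniform(0.9, 1.5)
        frames.append(df)
    true_df = pd.concat(frames, ignore_index=True)
    true_conc = ConcentrationTable(true_df)
    spectra = render_spectra(true_conc, cfg.library, prof, seed=render_rng)
    measured = simulate_reference_measurement(true_conc, cfg.reference_base_sd, seed=ref_rng)
    return CampaignResult(spectra, true_conc, measured, cfg)
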