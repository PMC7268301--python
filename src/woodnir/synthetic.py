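"""Synthetic solid-wood NIR spectra with planted, known structure.

The generator emulates the data regime of diffuse-reflectance FT-NIR
scans of increment cores: a smooth quadratic baseline, Gaussian
overtone/combination bands, per-spectrum multiplicative and additive
scatter, and white noise. Bands play one of four roles:

* ``trait_only``      — amplitude driven by extractives content (EC, %
  dry mass); placed near 6000 and 5400 cm^-1 where C-H overtone bands of
  extractives absorb free of grain-angle influence,
* ``confounder_only`` — driven by the grain-angle indicator (1 at 90
  degrees); placed in 8200-7800 cm^-1 where surface/cellulose effects of
  the presented core face dominate,
* ``shared``          — driven by EC plus a grain-angle offset (the
  overlap region near 8500 cm^-1 that makes naive calibration pick up
  the confounder),
* ``inert``           — constant structure (water bands near 7070 and
  5100 cm^-1 and broad background).

Every generated set carries a :class:`SyntheticTruth` with the planted
per-sample EC and angle and the wavenumber support of each band role, so
selection methods can be scored against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dataset import SpectraSet, default_axis
from .errors import ConfigError

ROLES = ("trait_only", "confounder_only", "shared", "inert")


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian absorption band.

    ``amplitude`` is in absorbance units per unit of the driving variable
    (per % EC for trait bands, per angle indicator for confounder bands,
    absolute for inert bands). The two gain terms apply to shared bands
    only; their drive is

        EC * (1 + angle_ec_gain * 1{angle=90}) + angle_gain * 1{angle=90}

    ``angle_gain`` is an additive offset (the cross section mimics that
    many percentage points of EC), while ``angle_ec_gain`` is a
    fractional change of the band's apparent EC sensitivity when the
    cross section is presented (a path-length/tissue effect). The
    multiplicative term is what makes the confounding resistant to
    implicit linear correction: no linear combination of wavenumbers can
    reproduce the EC-by-angle product.
    """

    center: float           # cm^-1
    width: float            # Gaussian sigma (or edge transition width), cm^-1
    role: str
    amplitude: float
    angle_gain: float = 0.0
    angle_ec_gain: float = 0.0
    shape: str = "gauss"    # "gauss" absorption band or "edge" shoulder step

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ConfigError(f"unknown band role {self.role!r}; choose from {ROLES}")
        if self.width <= 0:
            raise ConfigError(f"band width must be > 0 (got {self.width})")
        if self.shape not in ("gauss", "edge"):
            raise ConfigError(f"unknown band shape {self.shape!r}")

    def profile(self, wavenumbers: np.ndarray) -> np.ndarray:
        z = (wavenumbers - self.center) / self.width
        if self.shape == "edge":
            # sigmoid shoulder: a step of height `amplitude` whose first
            # derivative is a Gaussian bump centred on `center`
            from scipy.special import erf

            return 0.5 * (1.0 + erf(z / np.sqrt(2.0)))
        return np.exp(-0.5 * z**2)

    def support(self, wavenumbers: np.ndarray) -> np.ndarray:
        """Indices within one sigma of the band centre."""
        return np.flatnonzero(np.abs(wavenumbers - self.center) <= self.width)


def _default_bands() -> tuple[BandSpec, ...]:
    return (
        # extractives C-H overtone region, free of angle influence
        BandSpec(center=6000.0, width=80.0, role="trait_only", amplitude=0.0048),
        BandSpec(center=5400.0, width=70.0, role="trait_only", amplitude=0.0038),
        # grain-angle (presented face) region: scattering shoulders whose
        # derivative carries angle signal across their full support
        BandSpec(center=8100.0, width=70.0, role="confounder_only", amplitude=0.037,
                 shape="edge"),
        BandSpec(center=7800.0, width=50.0, role="confounder_only", amplitude=-0.037,
                 shape="edge"),
        # overlap region: EC band that also shifts with the presented face
        BandSpec(center=8500.0, width=70.0, role="shared", amplitude=0.0045,
                 angle_gain=1.5),
        # inert structure: water bands and broad background
        BandSpec(center=7070.0, width=130.0, role="inert", amplitude=0.28),
        BandSpec(center=5100.0, width=110.0, role="inert", amplitude=0.34),
        BandSpec(center=4300.0, width=160.0, role="inert", amplitude=0.22),
        BandSpec(center=8800.0, width=200.0, role="inert", amplitude=0.10),
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; the defaults define the standard benchmark.

    EC is drawn uniform over the observed field range 1.23-16.49 % dry
    mass. With ``paired_cores`` (the default, matching how increment
    cores are actually scanned) samples come in core pairs: each core
    contributes one spectrum per presented face, 0 and 90 degrees, with
    the same EC; ``n_samples`` must then be even. Otherwise each sample
    is an independent core whose angle is 90 with probability
    ``angle_fraction``. Scatter is a per-spectrum lognormal
    multiplicative factor and Gaussian additive offset; ``noise_sd`` is
    white noise in absorbance units; ``confounder_jitter_sd`` is the
    spread of the per-spectrum surface-condition factor that scales how
    strongly the presented face expresses itself in the confounder
    bands.
    """

    n_samples: int = 236
    axis: tuple[float, float, float] = (9000.0, 4000.0, -10.0)  # start, stop, step
    bands: tuple[BandSpec, ...] = field(default_factory=_default_bands)
    ec_range: tuple[float, float] = (1.23, 16.49)
    angle_fraction: float = 0.5
    paired_cores: bool = True
    scatter_mult_sd: float = 0.10
    scatter_add_sd: float = 0.02
    noise_sd: float = 0.013
    confounder_jitter_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.ec_range
        if not lo < hi:
            raise ConfigError(f"ec_range low must be < high (got {self.ec_range})")
        if not 0.0 < self.angle_fraction < 1.0:
            raise ConfigError(f"angle_fraction must be in (0, 1) (got {self.angle_fraction})")
        if self.paired_cores and self.n_samples % 2:
            raise ConfigError(
                f"paired_cores requires an even n_samples (got {self.n_samples})"
            )
        for sd in (self.scatter_mult_sd, self.scatter_add_sd, self.noise_sd,
                   self.confounder_jitter_sd):
            if sd < 0:
                raise ConfigError("scatter/noise SDs must be >= 0")
        wn = self.wavenumbers()
        lo_w, hi_w = wn.min(), wn.max()
        for b in self.bands:
            if not lo_w <= b.center <= hi_w:
                raise ConfigError(
                    f"band centre {b.center} cm^-1 outside axis [{lo_w}, {hi_w}]"
                )

    def wavenumbers(self) -> np.ndarray:
        start, stop, step = self.axis
        return default_axis(start, stop, step)


@dataclass
class SyntheticTruth:
    """Planted ground truth: per-sample drivers and band supports."""

    ec: np.ndarray
    angle: np.ndarray
    bands: tuple[BandSpec, ...]
    axis: np.ndarray

    def __post_init__(self) -> None:
        t = set(self.indices_for("trait_only"))
        c = set(self.indices_for("confounder_only"))
        if t & c:
            raise ConfigError(
                "trait_only and confounder_only band supports overlap; "
                "adjust band centres/widths"
            )

    def indices_for(self, role: str, wavenumbers: np.ndarray | None = None) -> np.ndarray:
        """Wavenumber indices within one sigma of any band of ``role``.

        Pass ``wavenumbers`` to resolve supports on a different axis than
        the generated one (e.g. after derivative edge truncation).
        """
        wn = self.axis if wavenumbers is None else np.asarray(wavenumbers, float)
        mask = np.zeros(wn.size, dtype=bool)
        for b in self.bands:
            if b.role == role:
                mask[b.support(wn)] = True
        return np.flatnonzero(mask)


def _baseline(wn: np.ndarray) -> np.ndarray:
    """Fixed smooth quadratic baseline (removed by derivatives)."""
    u = (wn - 6500.0) / 2500.0
    return 0.45 + 0.08 * u + 0.05 * u**2


def generate(cfg: SyntheticConfig) -> tuple[SpectraSet, SyntheticTruth]:
    """Draw one synthetic spectral data set; reproducible from cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    wn = cfg.wavenumbers()
    n, p = cfg.n_samples, wn.size

    if cfg.paired_cores:
        n_cores = n // 2
        ec_core = rng.uniform(*cfg.ec_range, size=n_cores)
        ec = np.repeat(ec_core, 2)
        is90 = np.tile([False, True], n_cores)
        core = np.repeat([f"c{i:04d}" for i in range(n_cores)], 2)
        ids = [f"c{i:04d}_a{90 if j else 0}" for i in range(n_cores) for j in (0, 1)]
    else:
        ec = rng.uniform(*cfg.ec_range, size=n)
        is90 = rng.random(n) < cfg.angle_fraction
        core = np.array([f"c{i:04d}" for i in range(n)])
        ids = [f"c{i:04d}_a{90 if a else 0}" for i, a in enumerate(is90)]
    angle = np.where(is90, 90.0, 0.0)
    # per-sample surface-condition factor: the strength with which the
    # presented face expresses itself varies between cores, so the
    # confounder bands are an imperfect readout of the angle
    surface = 1.0 + rng.normal(0.0, cfg.confounder_jitter_sd, size=n)

    signal = np.tile(_baseline(wn), (n, 1))
    for b in cfg.bands:
        if b.role == "trait_only":
            drive = ec
        elif b.role == "confounder_only":
            drive = is90 * surface
        elif b.role == "shared":
            drive = ec * (1.0 + b.angle_ec_gain * is90) + b.angle_gain * is90
        else:  # inert
            drive = np.ones(n)
        signal += np.outer(b.amplitude * drive, b.profile(wn))

    mult = rng.lognormal(mean=0.0, sigma=cfg.scatter_mult_sd, size=n)
    add = rng.normal(0.0, cfg.scatter_add_sd, size=n)
    noise = rng.normal(0.0, cfg.noise_sd, size=(n, p))
    absorbance = signal * mult[:, None] + add[:, None] + noise

    meta = pd.DataFrame(
        {"core_id": core, "ec": ec, "angle": angle},
        index=pd.Index(ids, name="sample_id"),
    )
    s = SpectraSet(wavenumbers=wn, absorbance=absorbance, sample_ids=ids, meta=meta)
    truth = SyntheticTruth(ec=ec, angle=angle, bands=cfg.bands, axis=wn)
    return s, truth


def default_benchmark(
    seed: int, cfg: SyntheticConfig | None = None
) -> tuple[SpectraSet, SpectraSet, SyntheticTruth]:
    """The standard deconfounding benchmark: ~200 calibration spectra
    plus a held-out validation set.

    Generates paired-core spectra under the default configuration (118
    cores, two faces each) and partitions them by Kennard-Stone on the
    SNV + 1st-derivative pre-processed matrix (the model-space
    geometry). In the paired design the split is made at the core level
    on core-averaged spectra, so both faces of a core land in the same
    set and no extractives value is shared between calibration and
    validation: 100 cores (200 spectra) calibrate, 18 cores (36
    spectra) validate.
    """
    from .dataset import average_replicates
    from .preprocess import PreprocessConfig, apply_pretreatment
    from .sampling import kennard_stone

    if cfg is None:
        cfg = SyntheticConfig(seed=seed)
    else:
        cfg = replace(cfg, seed=seed)
    s, truth = generate(cfg)
    pre = apply_pretreatment(s, PreprocessConfig(method="snv_sg1"))
    if cfg.paired_cores:
        cores = average_replicates(pre, "core_id")
        n_cal_cores = min(100, cores.n_samples - 2)
        split = kennard_stone(cores.absorbance, n_cal_cores)
        cal_cores = {cores.sample_ids[i] for i in split.cal_indices}
        cal_rows = [i for i, c in enumerate(s.meta["core_id"]) if c in cal_cores]
        val_rows = [i for i, c in enumerate(s.meta["core_id"]) if c not in cal_cores]
        return s.subset(cal_rows), s.subset(val_rows), truth
    n_cal = min(200, s.n_samples - 2)
    split = kennard_stone(pre.absorbance, n_cal)
    return s.subset(split.cal_indices), s.subset(split.val_indices), truth
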