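"""Synthetic populations of heterogeneously stained, nanochannel-confined DNA.

This module is the ground-truth generator for the whole pipeline.  It
emulates the experiment the downstream stages are built for: λ-DNA molecules
stained with a bis-intercalating dye (YOYO-1) at substoichiometric ratios,
loaded into ~100 nm nanochannels and imaged as a time series.  Each molecule
carries a *saturation* θ ∈ [0, 1] — its dye load as a fraction of the
nearest-neighbour-exclusion maximum of one dye per 4 bp — drawn from a
continuous distribution whose spread models the slow, heterogeneous binding
of the dye.  Extension grows affinely with θ (intercalation lengthens the
contour by ``dye_extension_nm`` per bound dye), total emission grows
linearly with θ, and image stacks are rendered with a Gaussian PSF, Poisson
shot noise, Gaussian read noise, slow centre diffusion and extension
fluctuations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

from .model import erf_box

__all__ = [
    "SimConfig",
    "MoleculeTruth",
    "ImageStack",
    "sample_dye_loads",
    "equilibrate_dye",
    "true_extension",
    "saturated_intensity",
    "make_molecule_truth",
    "render_frame",
    "render_stack",
    "simulate_population",
]


@dataclass(frozen=True)
class SimConfig:
    """Physical and optical parameters of one simulated condition.

    Lengths are in µm unless the field name says otherwise.  The dye
    stoichiometry defaults encode the intercalation model: at saturation
    (one dye per ``dye_site_bp`` = 4 bp) each dye adds ``dye_extension_nm``
    = 0.51 nm of contour, i.e. a relative contour increase of
    0.51 / (4 × 0.34) = 37.5 %.  ``native_extension_um`` is the extension
    of the dye-free molecule for this buffer condition and channel size; it
    is condition-specific and has no universal default.
    """

    genome_size_bp: int = 48_500
    rise_per_bp_nm: float = 0.34
    dye_site_bp: int = 4
    dye_extension_nm: float = 0.51
    native_extension_um: float = 5.0
    pixel_size_um: float = 0.16
    psf_sigma_px: float = 1.0
    frames_per_molecule: int = 200
    exposure_s: float = 0.1
    background_level: float = 20.0      # photons / pixel / frame
    read_noise_sd: float = 3.0          # photons rms per pixel
    saturated_plateau: float = 800.0    # transverse-summed photons / px at θ=1
    n_transverse_px: int = 5
    channel_length_px: int | None = None
    extension_fluct_sd_um: float = 0.3
    center_diffusion_step_um: float = 0.05
    molecule_extension_sd_um: float = 0.15
    ar_coeff: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_size_bp <= 0:
            raise ValueError("genome_size_bp must be positive")
        if self.dye_site_bp < 1:
            raise ValueError("dye_site_bp must be >= 1")
        for name in (
            "rise_per_bp_nm",
            "dye_extension_nm",
            "native_extension_um",
            "pixel_size_um",
            "psf_sigma_px",
            "exposure_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.frames_per_molecule < 1:
            raise ValueError("frames_per_molecule must be >= 1")
        if not 0.0 <= self.ar_coeff < 1.0:
            raise ValueError("ar_coeff must lie in [0, 1)")

    @property
    def max_saturation_dye_per_bp(self) -> float:
        return 1.0 / self.dye_site_bp

    @property
    def extension_slope(self) -> float:
        """Relative extension increase at full saturation (0.375 at defaults)."""
        return self.dye_extension_nm / (self.dye_site_bp * self.rise_per_bp_nm)


@dataclass(frozen=True)
class MoleculeTruth:
    """Ground truth for one simulated molecule."""

    saturation: float
    mean_extension_um: float
    plateau_amplitude: float            # transverse-summed photons / px
    extension_fluct_sd_um: float
    center_diffusion_step_um: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.saturation <= 1.0:
            raise ValueError("saturation must lie in [0, 1]")
        if self.mean_extension_um <= 0:
            raise ValueError("mean_extension_um must be positive")

    @property
    def integrated_intensity(self) -> float:
        """Whole-molecule emission, photons·µm per frame (transverse-summed)."""
        return self.plateau_amplitude * self.mean_extension_um


@dataclass
class ImageStack:
    """A time series of 2D photon-count frames for one molecule.

    ``frames`` has shape (n_frames, n_transverse, n_along); axis 1 is the
    transverse direction, axis 2 runs along the channel.
    """

    frames: np.ndarray
    pixel_size_um: float
    exposure_s: float
    truth: MoleculeTruth | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, ny, nx) array")
        if np.any(self.frames < 0):
            raise ValueError("photon counts must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


# ---------------------------------------------------------------------------
# Dye-load population model


def sample_dye_loads(
    n_molecules: int,
    mean_dye_per_bp: float,
    heterogeneity: float,
    seed: int | np.random.Generator,
    dye_site_bp: int = 4,
) -> np.ndarray:
    """Draw per-molecule dye saturations θ for a freshly mixed sample.

    The sample-average stoichiometry fixes the mean, mean(θ) =
    ``dye_site_bp × mean_dye_per_bp``; ``heterogeneity`` sets the spread of
    a Beta distribution on [0, 1] around that mean (0 → every molecule at
    exactly the mean, larger → wider, modelling slower dye equilibration).
    The Beta family is the simplest continuous two-parameter law on [0, 1]
    with a freely chosen mean, matching the observation that staining varies
    continuously rather than splitting into two discrete fractions.
    """
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    if heterogeneity < 0:
        raise ValueError("heterogeneity must be >= 0")
    if not 0.0 < mean_dye_per_bp <= 1.0 / dye_site_bp:
        raise ValueError(
            f"mean_dye_per_bp must be in (0, 1/{dye_site_bp}]: saturation is "
            f"one dye per {dye_site_bp} bp"
        )
    mean_theta = dye_site_bp * mean_dye_per_bp
    if heterogeneity == 0.0:
        return np.full(n_molecules, mean_theta)
    rng = np.random.default_rng(seed)
    # Beta concentration kappa = 2/heterogeneity: variance
    # m(1-m)/(kappa+1) increases monotonically with heterogeneity.
    kappa = 2.0 / heterogeneity
    a = mean_theta * kappa
    b = (1.0 - mean_theta) * kappa
    if mean_theta >= 1.0:
        return np.full(n_molecules, 1.0)
    return rng.beta(a, b, size=n_molecules)


def equilibrate_dye(
    loads: Sequence[float],
    relaxation_rate: float,
    duration: float,
    seed: int | np.random.Generator | None = None,
    exchange_sd: float = 0.0,
) -> np.ndarray:
    """Relax per-molecule dye loads toward the sample mean.

    Models the slow intermolecular redistribution of dye (accelerated by
    heat and ionic strength) as first-order relaxation of each θ_i toward
    the cohort mean with rate ``relaxation_rate`` (1/h) over ``duration``
    hours.  Total dye is conserved exactly: the mean of the output equals
    the mean of the input for every rate and duration.  ``exchange_sd``
    adds an optional re-centred Gaussian perturbation (stochastic exchange)
    scaled by the unrelaxed fraction; it preserves the mean exactly but can
    push individual values slightly outside [0, 1], so it defaults to 0.
    """
    loads = np.asarray(loads, dtype=float)
    if np.any((loads < 0) | (loads > 1)):
        raise ValueError("all loads must lie in [0, 1]")
    if relaxation_rate < 0:
        raise ValueError("relaxation_rate must be >= 0")
    if duration < 0:
        raise ValueError("duration must be >= 0")
    mean = loads.mean()
    remaining = math.exp(-relaxation_rate * duration)
    out = mean + (loads - mean) * remaining
    if exchange_sd > 0 and loads.size > 1:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, exchange_sd * remaining, size=loads.shape)
        out = out + noise - noise.mean()
    return out


def true_extension(saturation, config: SimConfig):
    """Mean extension (µm) of a molecule at dye saturation θ.

    Affine intercalation law: extension = native × (1 + θ·s) with relative
    slope s = dye_extension_nm / (dye_site_bp × rise_per_bp_nm).  Both the
    contour increase and the confined extension scale by the same relative
    factor, so the native-to-contour extension ratio drops out.
    """
    theta = np.asarray(saturation, dtype=float)
    if np.any((theta < 0) | (theta > 1)):
        raise ValueError("saturation must lie in [0, 1]")
    out = config.native_extension_um * (1.0 + theta * config.extension_slope)
    return float(out) if np.isscalar(saturation) else out


def saturated_intensity(config: SimConfig) -> float:
    """Whole-molecule emission (photons·µm/frame) of a fully stained molecule."""
    return config.saturated_plateau * true_extension(1.0, config)


def make_molecule_truth(
    saturation: float,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> MoleculeTruth:
    """Build the ground truth for one molecule at saturation θ.

    The whole-molecule emission is linear in the amount of dye bound,
    I(θ) = θ × I(1); the plateau amplitude is that emission spread over the
    molecule's extension.  With ``rng`` given, a molecule-level extension
    scatter (``molecule_extension_sd_um``; channel-to-channel and molecule-
    to-molecule variability) is added around the intercalation law.
    """
    ext = true_extension(saturation, config)
    if rng is not None and config.molecule_extension_sd_um > 0:
        ext = max(
            ext + rng.normal(0.0, config.molecule_extension_sd_um),
            0.2 * config.native_extension_um,
        )
    plateau = saturation * saturated_intensity(config) / ext
    return MoleculeTruth(
        saturation=float(saturation),
        mean_extension_um=float(ext),
        plateau_amplitude=float(plateau),
        extension_fluct_sd_um=config.extension_fluct_sd_um,
        center_diffusion_step_um=config.center_diffusion_step_um,
    )


# ---------------------------------------------------------------------------
# Rendering


def _channel_length_px(config: SimConfig, max_extension_um: float) -> int:
    if config.channel_length_px is not None:
        return int(config.channel_length_px)
    margin_px = 3.0 * config.psf_sigma_px + 4.0
    return int(math.ceil(max_extension_um / config.pixel_size_um + 2 * margin_px))


def _edge_margin_um(config: SimConfig) -> float:
    """Clearance required beyond each blurred edge: 3σ of blur plus 3 px."""
    return (3.0 * config.psf_sigma_px + 3.0) * config.pixel_size_um


def frame_expectation(
    truth: MoleculeTruth,
    center_um: float,
    config: SimConfig,
    extension_um: float | None = None,
    n_along_px: int | None = None,
) -> np.ndarray:
    """Noiseless expected photon counts for one frame.

    The transverse-summed profile along the channel follows the blurred-box
    model with plateau A = ``truth.plateau_amplitude`` and background
    ``n_transverse_px × background_level``; transversely the signal is a
    normalized Gaussian of width ``psf_sigma_px`` centred mid-channel.
    """
    w = truth.mean_extension_um if extension_um is None else float(extension_um)
    nx = n_along_px or _channel_length_px(config, w)
    margin = _edge_margin_um(config)
    fov_um = nx * config.pixel_size_um
    if center_um - w / 2 - margin < 0 or center_um + w / 2 + margin > fov_um:
        raise ValueError(
            "field too small: molecule (with blurred edges) does not fit with "
            "a 3 px margin; enlarge channel_length_px"
        )
    x_um = (np.arange(nx) + 0.5) * config.pixel_size_um
    along = erf_box(
        x_um,
        center_um,
        w,
        truth.plateau_amplitude,
        0.0,
        config.psf_sigma_px * config.pixel_size_um,
    )
    rows = np.arange(config.n_transverse_px, dtype=float)
    g = np.exp(-0.5 * ((rows - (config.n_transverse_px - 1) / 2.0) / config.psf_sigma_px) ** 2)
    g /= g.sum()
    return config.background_level + np.outer(g, along)


def render_frame(
    truth: MoleculeTruth,
    center_um: float,
    config: SimConfig,
    seed: int | np.random.Generator | None = None,
    noiseless: bool = False,
    extension_um: float | None = None,
    n_along_px: int | None = None,
) -> np.ndarray:
    """Render one frame: Poisson shot noise on the expectation plus Gaussian
    read noise, clipped at zero.  ``noiseless=True`` returns the expectation.
    Identical seeds give identical frames."""
    mu = frame_expectation(truth, center_um, config, extension_um, n_along_px)
    if noiseless:
        return mu
    rng = np.random.default_rng(seed)
    counts = rng.poisson(mu).astype(float)
    if config.read_noise_sd > 0:
        counts += rng.normal(0.0, config.read_noise_sd, size=mu.shape)
    return np.clip(counts, 0.0, None)


def render_stack(
    truth: MoleculeTruth,
    config: SimConfig,
    seed: int | np.random.Generator | None = None,
    noiseless: bool = False,
) -> ImageStack:
    """Render a full time series for one molecule.

    The centre performs a bounded (reflected) Gaussian random walk with step
    ``center_diffusion_step_um``; the per-frame extension follows a
    stationary AR(1) process with mean ``mean_extension_um``, stationary
    standard deviation ``extension_fluct_sd_um`` and lag-1 correlation
    ``ar_coeff``, truncated below at half the mean extension.
    """
    rng = np.random.default_rng(seed)
    n = config.frames_per_molecule
    w_mean = truth.mean_extension_um
    w_sd = truth.extension_fluct_sd_um
    w_max = w_mean + (4.0 * w_sd if w_sd > 0 else 0.0)
    nx = _channel_length_px(config, w_max)
    fov_um = nx * config.pixel_size_um
    margin = _edge_margin_um(config)
    lo = w_max / 2.0 + margin
    hi = fov_um - lo
    if hi <= lo:
        raise ValueError("field too small: no admissible centre positions")

    phi = config.ar_coeff
    if w_sd > 0:
        w = np.empty(n)
        w[0] = rng.normal(w_mean, w_sd)
        innov_sd = w_sd * math.sqrt(1.0 - phi * phi)
        for t in range(1, n):
            w[t] = w_mean + phi * (w[t - 1] - w_mean) + rng.normal(0.0, innov_sd)
        w = np.clip(w, 0.5 * w_mean, w_max)
    else:
        w = np.full(n, w_mean)

    c = np.empty(n)
    c[0] = 0.5 * fov_um
    step = truth.center_diffusion_step_um
    for t in range(1, n):
        c[t] = c[t - 1] + (rng.normal(0.0, step) if step > 0 else 0.0)
        # reflect into the admissible interval
        if c[t] < lo:
            c[t] = lo + (lo - c[t])
        if c[t] > hi:
            c[t] = hi - (c[t] - hi)
        c[t] = min(max(c[t], lo), hi)

    frames = np.empty((n, config.n_transverse_px, nx))
    for t in range(n):
        frames[t] = render_frame(
            truth,
            c[t],
            config,
            seed=rng,
            noiseless=noiseless,
            extension_um=w[t],
            n_along_px=nx,
        )
    return ImageStack(
        frames=frames,
        pixel_size_um=config.pixel_size_um,
        exposure_s=config.exposure_s,
        truth=truth,
    )


def simulate_population(
    saturations: Sequence[float],
    config: SimConfig,
    master_seed: int,
    noiseless: bool = False,
) -> Iterator[tuple[int, MoleculeTruth, ImageStack]]:
    """Yield (molecule_id, truth, stack) for each saturation in turn.

    Per-molecule randomness is derived deterministically from ``master_seed``
    via numpy seed-sequence spawning, so populations are reproducible and
    individual molecules are independent.
    """
    children = np.random.SeedSequence(master_seed).spawn(len(saturations))
    for i, (theta, child) in enumerate(zip(saturations, children)):
        rng = np.random.default_rng(child)
        truth = make_molecule_truth(float(theta), config, rng=rng)
        stack = render_stack(truth, config, seed=rng, noiseless=noiseless)
        yield i, truth, stack
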