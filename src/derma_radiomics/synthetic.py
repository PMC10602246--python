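"""Synthetic longitudinal skin-image cohorts.

Emulates the measurement design of a close-up skin imaging study during
whole-breast radiotherapy: for each patient, images at four anatomical
points per breast (upper / lower / inner / outer, 3 cm from the nipple),
on both the treated (ipsilateral) and untreated (contralateral) breast,
in three device illumination modes (normal, polarized, UV), at four time
points (before treatment, ~day 7, ~day 14, and ~10 days after the end of
treatment).  Point skin doses in cGy are drawn around the means reported
for such cohorts and drive a severity signal that darkens the treated
side and adds blotchy textural heterogeneity over time; the untreated
side receives a small dose-independent echo of the same signal.

The generator is fully deterministic given the master seed: every image
gets its own random substream derived by hashing its metadata, so any
single image can be regenerated without producing the whole cohort.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter, zoom

__all__ = [
    "SyntheticConfig",
    "DoseRecord",
    "SkinImage",
    "ConfigError",
    "POINT_SITES",
    "SIDES",
    "sample_doses",
    "severity",
    "render_image",
    "generate_cohort",
    "iter_cohort",
    "cohort_manifest",
]

POINT_SITES = ("upper", "lower", "inner", "outer")
SIDES = ("ipsilateral", "contralateral")
TIMEPOINTS = ("Before_RT", "RT_D7", "RT_D14", "After_RT_D10")
MODES = ("normal", "polarized", "uv")


class ConfigError(ValueError):
    """Invalid synthetic-cohort configuration."""


@dataclass(frozen=True)
class SkinImage:
    """One RGB capture with its acquisition metadata."""

    pixels: np.ndarray  # H x W x 3 uint8
    patient_id: str
    side: str
    point_site: str
    mode: str
    timepoint: str


@dataclass(frozen=True)
class DoseRecord:
    """Measured skin dose (cGy) at one point of the treated breast."""

    patient_id: str
    point_site: str
    dose: float


def _default_dose_means() -> dict[str, float]:
    # cohort means reported for first-fraction OSLD point doses (cGy)
    return {"upper": 253.1, "lower": 247.8, "inner": 212.4, "outer": 226.8}


def _default_dose_sds() -> dict[str, float]:
    return {"upper": 14.7, "lower": 18.1, "inner": 19.6, "outer": 23.5}


def _default_base_means() -> dict[str, float]:
    # normal light is brightest; UV captures are markedly darker
    return {"normal": 150.0, "polarized": 135.0, "uv": 90.0}


def _default_severity_profile() -> dict[str, dict[str, float]]:
    # monotone accumulation in all three modes: visible damage builds
    # through treatment and has not resolved ten days after the end;
    # polarized / UV (melanin pigmentation) accumulate more slowly at
    # first but keep rising
    return {
        "normal": {"Before_RT": 0.0, "RT_D7": 0.5, "RT_D14": 0.85, "After_RT_D10": 1.0},
        "polarized": {"Before_RT": 0.0, "RT_D7": 0.4, "RT_D14": 0.7, "After_RT_D10": 1.0},
        "uv": {"Before_RT": 0.0, "RT_D7": 0.5, "RT_D14": 0.8, "After_RT_D10": 1.0},
    }


def _default_channel_weights() -> dict[str, tuple[float, float, float]]:
    return {m: (1.0, 1.0, 1.0) for m in MODES}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort.

    Intensity units are 8-bit counts (0-255), lengths are pixels and
    doses are cGy.  ``kappa_dark`` is the mean-intensity drop at unit
    severity; ``kappa_het`` the amplitude of the severity-scaled blotch
    field.  ``contralateral_attenuation`` (gamma) scales the untreated
    side's dose-independent severity.
    """

    n_patients: int = 20
    image_height: int = 1212
    image_width: int = 1624
    modes: tuple[str, ...] = MODES
    timepoints: tuple[str, ...] = TIMEPOINTS
    dose_means: dict[str, float] = field(default_factory=_default_dose_means)
    dose_sds: dict[str, float] = field(default_factory=_default_dose_sds)
    base_mean_intensity: dict[str, float] = field(default_factory=_default_base_means)
    base_texture_sd: float = 12.0
    correlation_length: float = 10.0
    blotch_correlation_length: float = 40.0
    speckle_density: float = 0.002
    speckle_depth: float = 45.0
    kappa_dark: float = 30.0
    kappa_het: float = 25.0
    severity_profile: dict[str, dict[str, float]] = field(
        default_factory=_default_severity_profile
    )
    channel_weights: dict[str, tuple[float, float, float]] = field(
        default_factory=_default_channel_weights
    )
    contralateral_attenuation: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        if self.image_height < 2 or self.image_width < 2:
            raise ConfigError("image dimensions must be >= 2 pixels")
        for site in POINT_SITES:
            if site not in self.dose_means or site not in self.dose_sds:
                raise ConfigError(f"missing dose parameters for site {site!r}")
            if self.dose_sds[site] <= 0:
                raise ConfigError(f"dose SD for site {site!r} must be > 0")
        g = self.contralateral_attenuation
        if not 0.0 <= g <= 1.0:
            raise ConfigError("contralateral_attenuation must lie in [0, 1]")
        if not 0.0 <= self.speckle_density <= 1.0:
            raise ConfigError("speckle_density must lie in [0, 1]")
        for mode in self.modes:
            prof = self.severity_profile.get(mode)
            if prof is None:
                raise ConfigError(f"no severity profile for mode {mode!r}")
            if prof.get(self.timepoints[0], None) != 0.0:
                raise ConfigError("severity profile must be 0 at the baseline timepoint")
            if any(w < 0 for w in prof.values()):
                raise ConfigError("severity weights must be non-negative")

    @property
    def reference_dose(self) -> float:
        """Cohort-level reference dose (cGy): mean of the site means."""
        return float(np.mean([self.dose_means[s] for s in POINT_SITES]))

    def with_(self, **kwargs) -> "SyntheticConfig":
        return replace(self, **kwargs)


def _substream(master_seed: int, *key) -> np.random.Generator:
    """Deterministic per-entity RNG derived from the master seed.

    Hashing (not Python's salted ``hash``) so cohorts are reproducible
    across processes and any image is independently regenerable.
    """
    token = "|".join([str(master_seed), *map(str, key)])
    digest = hashlib.blake2b(token.encode(), digest_size=8).digest()
    sub = int.from_bytes(digest, "little") % (2**31)
    return np.random.default_rng(np.random.SeedSequence([master_seed % (2**31), sub]))


def sample_doses(config: SyntheticConfig, patient_id: str) -> list[DoseRecord]:
    """Draw the four ipsilateral point doses for one patient.

    Normal draws around the configured per-site mean/SD, truncated at
    zero (resampling); deterministic given (seed, patient_id).
    """
    config.validate()
    rng = _substream(config.seed, "dose", patient_id)
    records = []
    for site in POINT_SITES:
        mu, sd = config.dose_means[site], config.dose_sds[site]
        dose = rng.normal(mu, sd)
        while dose <= 0:  # truncation; essentially never triggers at defaults
            dose = rng.normal(mu, sd)
        records.append(DoseRecord(patient_id=patient_id, point_site=site, dose=float(dose)))
    return records


def severity(config: SyntheticConfig, side: str, timepoint: str, dose: float, mode: str) -> float:
    """Dimensionless injury severity for one image.

    Treated side: w_mode(t) * dose / reference dose.  Untreated side:
    gamma * w_mode(t), dose-independent (no contralateral dosimetry is
    modelled).  Zero at baseline for both sides.
    """
    if timepoint not in config.timepoints:
        raise ValueError(f"unknown timepoint {timepoint!r}")
    if side not in SIDES:
        raise ValueError(f"unknown side {side!r}")
    w = config.severity_profile[mode][timepoint]
    if side == "ipsilateral":
        return w * dose / config.reference_dose
    return config.contralateral_attenuation * w


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], corr_len: float) -> np.ndarray:
    """Zero-mean, unit-variance Gaussian random field with the given
    spatial correlation length (pixels).

    Long-range fields (correlation length >= 20 px) are synthesised on
    a coarse grid and bilinearly upsampled, which preserves the field's
    large-scale structure at a fraction of the filtering cost.
    """
    factor = int(corr_len // 5)
    if factor >= 4:
        h = -(-shape[0] // factor) + 2
        w = -(-shape[1] // factor) + 2
        z = rng.standard_normal((h, w)).astype(np.float32)
        f = gaussian_filter(z, sigma=corr_len / factor, truncate=3.0)
        f = zoom(f, factor, order=1)[: shape[0], : shape[1]]
    else:
        z = rng.standard_normal(shape).astype(np.float32)
        f = gaussian_filter(z, sigma=corr_len, truncate=3.0)
    f -= f.mean()
    sd = f.std()
    if sd > 0:
        f /= sd
    return f


def _base_field(config: SyntheticConfig, patient_id: str, side: str, point_site: str, mode: str) -> np.ndarray:
    """Patient/point-specific base skin texture, shared by all timepoints."""
    shape = (config.image_height, config.image_width)
    rng = _substream(config.seed, "base", patient_id, side, point_site, mode)
    base = config.base_mean_intensity[mode] + config.base_texture_sd * _smooth_field(
        rng, shape, config.correlation_length
    )
    if config.speckle_density > 0:
        pores = rng.random(shape) < config.speckle_density
        base[pores] -= config.speckle_depth
    return base


def _blotch_field(config: SyntheticConfig, patient_id: str, side: str, point_site: str, mode: str) -> np.ndarray:
    rng = _substream(config.seed, "blotch", patient_id, side, point_site, mode)
    return _smooth_field(
        rng, (config.image_height, config.image_width), config.blotch_correlation_length
    )


def render_image(
    config: SyntheticConfig,
    patient_id: str,
    side: str,
    point_site: str,
    mode: str,
    timepoint: str,
    dose: float,
    _base: np.ndarray | None = None,
    _blotch: np.ndarray | None = None,
) -> SkinImage:
    """Render one capture.

    pixels = clip( base − κ_dark·s − κ_het·s·blotch ) per channel, where
    s is the severity for (side, timepoint, dose).  The base and blotch
    fields depend only on (patient, side, point, mode), so across time
    only the severity term changes.  ``_base``/``_blotch`` allow callers
    iterating over timepoints to reuse the cached fields; passing them
    never changes the result.
    """
    config.validate()
    base = _base if _base is not None else _base_field(config, patient_id, side, point_site, mode)
    s = severity(config, side, timepoint, dose, mode)
    if s > 0:
        blotch = (
            _blotch
            if _blotch is not None
            else _blotch_field(config, patient_id, side, point_site, mode)
        )
        damage = config.kappa_dark * s + config.kappa_het * s * blotch
    else:
        damage = None
    weights = config.channel_weights[mode]
    if len(set(weights)) == 1:  # identical channels: quantize once
        chan = base if damage is None else base - weights[0] * damage
        q = np.clip(np.rint(chan), 0, 255).astype(np.uint8)
        pixels = np.stack([q, q, q], axis=-1)
    else:
        channels = []
        for w in weights:
            chan = base if damage is None else base - w * damage
            channels.append(np.clip(np.rint(chan), 0, 255).astype(np.uint8))
        pixels = np.stack(channels, axis=-1)
    return SkinImage(
        pixels=pixels,
        patient_id=patient_id,
        side=side,
        point_site=point_site,
        mode=mode,
        timepoint=timepoint,
    )


def _patient_ids(config: SyntheticConfig) -> list[str]:
    return [f"P{i + 1:03d}" for i in range(config.n_patients)]


def iter_cohort(config: SyntheticConfig) -> Iterator[tuple[SkinImage, float]]:
    """Stream every image of the cohort (with its driving dose) in a
    fixed deterministic order, caching base/blotch fields across the
    four timepoints of each (patient, side, point, mode) cell.

    A full-scale cohort does not fit in memory (20 patients x 96 images
    of 1624x1212x3 bytes), hence the generator interface.
    """
    config.validate()
    for pid in _patient_ids(config):
        doses = {r.point_site: r.dose for r in sample_doses(config, pid)}
        for side in SIDES:
            for site in POINT_SITES:
                dose = doses[site]
                for mode in config.modes:
                    base = _base_field(config, pid, side, site, mode)
                    blotch = _blotch_field(config, pid, side, site, mode)
                    for tp in config.timepoints:
                        yield render_image(
                            config, pid, side, site, mode, tp, dose,
                            _base=base, _blotch=blotch,
                        ), dose


def cohort_manifest(config: SyntheticConfig, root: str | Path = ".") -> pd.DataFrame:
    """Manifest of every image in the cohort design (one row per cell)."""
    root = Path(root)
    rows = []
    for pid in _patient_ids(config):
        for side in SIDES:
            for site in POINT_SITES:
                for mode in config.modes:
                    for tp in config.timepoints:
                        rows.append(
                            {
                                "patient_id": pid,
                                "side": side,
                                "point_site": site,
                                "mode": mode,
                                "timepoint": tp,
                                "path": str(root / f"{pid}_{side}_{site}_{mode}_{tp}.png"),
                            }
                        )
    return pd.DataFrame(rows)


def doses_frame(config: SyntheticConfig) -> pd.DataFrame:
    """All dose records of the cohort as a tidy frame."""
    rows = [
        {"patient_id": r.patient_id, "point_site": r.point_site, "dose_cGy": r.dose}
        for pid in _patient_ids(config)
        for r in sample_doses(config, pid)
    ]
    return pd.DataFrame(rows)


def generate_cohort(
    config: SyntheticConfig, out_dir: str | Path | None = None
) -> tuple[list[SkinImage] | None, pd.DataFrame, pd.DataFrame]:
    """Produce the full cohort.

    With ``out_dir`` the images are written as 8-bit RGB PNG files and
    ``(None, doses, manifest)`` is returned; without it all images are
    returned in memory (only sensible for reduced image sizes).
    """
    config.validate()
    doses = doses_frame(config)
    if out_dir is None:
        images = [img for img, _ in iter_cohort(config)]
        manifest = cohort_manifest(config)
        return images, doses, manifest
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = cohort_manifest(config, root=out)
    paths = manifest["path"].tolist()
    if len(set(paths)) != len(paths):
        raise ConfigError("overlapping output paths in manifest")
    for (img, _), path in zip(iter_cohort(config), paths):
        Image.fromarray(img.pixels, mode="RGB").save(path)
    doses.to_csv(out / "doses.csv", index=False)
    manifest.to_csv(out / "manifest.csv", index=False)
    return None, doses, manifest


def load_image(path: str | Path, meta: dict) -> SkinImage:
    """Read one 8-bit RGB PNG/TIFF capture back with its metadata."""
    arr = np.asarray(Image.open(path).convert("RGB"))
    return SkinImage(
        pixels=arr,
        patient_id=meta["patient_id"],
        side=meta["side"],
        point_site=meta["point_site"],
        mode=meta["mode"],
        timepoint=meta["timepoint"],
    )
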