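"""Synthetic assay images and phenotype panels with known ground truth.

Every stage of the pipeline is testable by parameter recovery:

* :func:`render_settling_image` draws a culture-tube photograph with a
  cleared supernatant band above a dense settled region, the boundary at a
  known fraction of the tube height;
* :func:`render_invasion_image` draws a washed agar-invasion spot of known
  mean intensity on a known background;
* :func:`simulate_panel` draws a multi-strain phenotype panel with a
  specified inter-phenotype correlation structure, per-phenotype diploid
  attenuation factors, ordinal 0-5 rubric thresholding and technical
  replicate noise.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import GeometryError, ValidationError
from .imaging import GrayImage, save_image

#: The six phenotypes scored in the panel, in display order.
DEFAULT_PHENOTYPES = (
    "colony",
    "mat",
    "flocculation",
    "invasion",
    "adhesion",
    "filamentous",
)

#: Default multiplicative effect of diploidy on the latent propensity.
#: Anchored to the observed haploid-vs-diploid attenuation pattern:
#: flocculation collapses in diploids, invasion is nearly unchanged,
#: polystyrene adhesion is strongly weakened, colony/mat complexity is
#: mildly attenuated, and filamentous growth is diploid-specific.
DEFAULT_DIPLOID_EFFECT = {
    "colony": 0.8,
    "mat": 0.9,
    "flocculation": 0.1,
    "invasion": 0.8,
    "adhesion": 0.3,
    "filamentous": 1.0,
}

#: Default ascending cut points mapping latent propensity to ordinal 0-5.
DEFAULT_ORDINAL_THRESHOLDS = (0.5, 1.0, 1.5, 2.0, 2.5)


@dataclass(frozen=True)
class TubeSpec:
    """Parameters for a synthetic settling-tube photograph.

    The line axis is vertical with the meniscus at the top; the cleared
    (low-gray) band occupies ``cleared_fraction`` of the height and the
    dense settled region (high gray) lies below it.
    """

    cleared_fraction: float
    width_px: int = 60
    height_px: int = 240
    clear_level: float = 30.0
    dense_level: float = 200.0
    boundary_softness_px: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px < 1 or self.height_px < 1:
            raise ValidationError("image dimensions must be positive")
        if not 0 <= self.cleared_fraction <= 1:
            raise ValidationError("cleared_fraction must lie in [0, 1]")
        if not (0 <= self.clear_level < self.dense_level <= 255):
            raise ValidationError("need 0 <= clear_level < dense_level <= 255")
        if self.boundary_softness_px < 0 or self.noise_sd < 0:
            raise ValidationError("softness and noise_sd must be nonnegative")


@dataclass(frozen=True)
class SpotSpec:
    """Parameters for a synthetic agar-invasion spot image."""

    image_width_px: int = 120
    image_height_px: int = 120
    background_level: float = 20.0
    spot_center: tuple[float, float] = (60.0, 60.0)
    spot_radius_px: float = 25.0
    spot_level: float = 120.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_width_px < 1 or self.image_height_px < 1:
            raise ValidationError("image dimensions must be positive")
        if self.spot_radius_px <= 0:
            raise ValidationError("spot_radius_px must be positive")
        for lvl in (self.background_level, self.spot_level):
            if not 0 <= lvl <= 255:
                raise ValidationError("levels must lie in [0, 255]")
        cx, cy = self.spot_center
        r = self.spot_radius_px
        if not (
            cx - r >= 0
            and cx + r <= self.image_width_px - 1
            and cy - r >= 0
            and cy + r <= self.image_height_px - 1
        ):
            raise GeometryError("spot must lie entirely inside the image")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be nonnegative")

    @property
    def truth(self) -> float:
        """Noise-free ground-truth corrected intensity."""
        return max(0.0, self.spot_level - self.background_level)


@dataclass(frozen=True)
class PanelSpec:
    """Parameters for a simulated strain x phenotype panel.

    Per strain, a latent propensity vector is drawn from a multivariate
    Gaussian with correlation ``latent_correlation`` and mapped to the
    nonnegative scale by a softplus transform centered at ``latent_loc``.
    Diploid propensities are the haploid ones multiplied by the
    per-phenotype ``diploid_effect`` (with per-strain exceptions), applied
    before technical replicate noise. Ordinal 0-5 scores threshold the
    noise-free latent value.
    """

    n_strains: int = 31
    phenotypes: tuple[str, ...] = DEFAULT_PHENOTYPES
    latent_correlation: np.ndarray | None = None
    diploid_effect: Mapping[str, float] | None = None
    exception_strains: Mapping[str, Mapping[str, float]] | None = None
    replicate_sd: float = 0.05
    n_technical: int = 3
    ordinal_thresholds: Mapping[str, Sequence[float]] | None = None
    latent_loc: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strains < 1 or self.n_technical < 1:
            raise ValidationError("n_strains and n_technical must be positive")
        if self.replicate_sd < 0:
            raise ValidationError("replicate_sd must be nonnegative")
        if len(set(self.phenotypes)) != len(self.phenotypes):
            raise ValidationError("phenotype names must be unique")

    def correlation_matrix(self) -> np.ndarray:
        p = len(self.phenotypes)
        if self.latent_correlation is None:
            return np.eye(p)
        corr = np.asarray(self.latent_correlation, dtype=float)
        if corr.shape != (p, p):
            raise ValidationError("correlation matrix shape must match phenotypes")
        if not np.allclose(corr, corr.T):
            raise ValidationError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(corr), 1.0):
            raise ValidationError("correlation matrix must have unit diagonal")
        eigvals = np.linalg.eigvalsh(corr)
        if eigvals.min() < -1e-8:
            raise ValidationError("correlation matrix must be positive semidefinite")
        return corr

    def effect_for(self, strain: str, phenotype: str) -> float:
        if self.exception_strains and phenotype in self.exception_strains.get(
            strain, {}
        ):
            return float(self.exception_strains[strain][phenotype])
        effects = (
            DEFAULT_DIPLOID_EFFECT if self.diploid_effect is None else self.diploid_effect
        )
        return float(effects.get(phenotype, 1.0))

    def thresholds_for(self, phenotype: str) -> np.ndarray:
        if self.ordinal_thresholds is None:
            cuts = DEFAULT_ORDINAL_THRESHOLDS
        else:
            cuts = self.ordinal_thresholds.get(phenotype, DEFAULT_ORDINAL_THRESHOLDS)
        arr = np.asarray(cuts, dtype=float)
        if len(arr) > 5 or np.any(np.diff(arr) <= 0):
            raise ValidationError("ordinal thresholds must be <=5 strictly ascending cuts")
        return arr


def _noisy(values: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    if sd == 0:
        return values
    return np.clip(values + rng.normal(0.0, sd, size=values.shape), 0.0, 255.0)


def render_settling_image(spec: TubeSpec) -> GrayImage:
    """Render a settling-tube image with the cleared/dense boundary at
    ``cleared_fraction x height``.

    With zero softness the transition is a hard step at that row; with
    positive softness the column profile ramps linearly from the clear to
    the dense level over ``boundary_softness_px`` rows, with the half-way
    point of the ramp at the boundary row.
    """
    rows = np.arange(spec.height_px, dtype=float)
    boundary = spec.cleared_fraction * spec.height_px
    if spec.boundary_softness_px == 0:
        frac_dense = (rows >= boundary).astype(float)
    else:
        frac_dense = np.clip(
            (rows - boundary) / spec.boundary_softness_px + 0.5, 0.0, 1.0
        )
    profile = spec.clear_level + (spec.dense_level - spec.clear_level) * frac_dense
    pixels = np.tile(profile[:, None], (1, spec.width_px))
    rng = np.random.default_rng(spec.seed)
    return GrayImage(_noisy(pixels, spec.noise_sd, rng))


def render_invasion_image(spec: SpotSpec) -> tuple[GrayImage, float]:
    """Render an invasion-spot image; returns the image and the noise-free
    ground-truth corrected intensity ``max(0, spot_level - background_level)``."""
    yy, xx = np.mgrid[0 : spec.image_height_px, 0 : spec.image_width_px]
    cx, cy = spec.spot_center
    inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= spec.spot_radius_px**2
    pixels = np.where(inside, spec.spot_level, spec.background_level).astype(float)
    rng = np.random.default_rng(spec.seed)
    return GrayImage(_noisy(pixels, spec.noise_sd, rng)), spec.truth


def _softplus(z: np.ndarray) -> np.ndarray:
    # numerically stable log(1 + exp(z))
    return np.logaddexp(0.0, z)


def simulate_panel(spec: PanelSpec) -> pd.DataFrame:
    """Simulate a long-format phenotype panel.

    Returns a DataFrame with columns ``strain, ploidy, phenotype,
    replicate_type, replicate_id, value, ordinal_score``; haploid and
    diploid strata are both present, with ``n_technical`` technical
    replicates per stratum. Reproducible for a fixed seed.
    """
    corr = spec.correlation_matrix()
    rng = np.random.default_rng(spec.seed)
    p = len(spec.phenotypes)
    # Gaussian copula via eigendecomposition (tolerates semidefinite targets)
    evals, evecs = np.linalg.eigh(corr)
    root = evecs @ np.diag(np.sqrt(np.clip(evals, 0.0, None)))
    z = rng.standard_normal((spec.n_strains, p)) @ root.T
    latent_h = _softplus(spec.latent_loc + z)

    width = max(3, len(str(spec.n_strains)))
    strains = [f"S{i + 1:0{width}d}" for i in range(spec.n_strains)]
    records = []
    for j, phen in enumerate(spec.phenotypes):
        cuts = spec.thresholds_for(phen)
        for i, strain in enumerate(strains):
            lat = {"haploid": latent_h[i, j]}
            lat["diploid"] = spec.effect_for(strain, phen) * lat["haploid"]
            for ploidy in ("haploid", "diploid"):
                score = int(np.searchsorted(cuts, lat[ploidy], side="right"))
                reps = _noisy(
                    np.full(spec.n_technical, lat[ploidy]), spec.replicate_sd, rng
                )
                for r, value in enumerate(reps, start=1):
                    records.append(
                        (strain, ploidy, phen, "technical", r, float(value), score)
                    )
    return pd.DataFrame.from_records(
        records,
        columns=[
            "strain",
            "ploidy",
            "phenotype",
            "replicate_type",
            "replicate_id",
            "value",
            "ordinal_score",
        ],
    )


# ---------------------------------------------------------------------------
# File output with ground-truth sidecars
# ---------------------------------------------------------------------------


def write_tube_image(spec: TubeSpec, path: str | Path) -> Path:
    """Write a rendered tube PNG plus a ``<name>.truth.csv`` sidecar."""
    path = Path(path)
    save_image(render_settling_image(spec), path)
    sidecar = path.with_suffix(".truth.csv")
    with open(sidecar, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["image", "cleared_fraction", "clear_level", "dense_level", "seed"])
        w.writerow(
            [path.name, spec.cleared_fraction, spec.clear_level, spec.dense_level, spec.seed]
        )
    return sidecar


def write_spot_image(spec: SpotSpec, path: str | Path) -> Path:
    """Write a rendered invasion-spot PNG plus a ground-truth sidecar CSV."""
    path = Path(path)
    image, truth = render_invasion_image(spec)
    save_image(image, path)
    sidecar = path.with_suffix(".truth.csv")
    with open(sidecar, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["image", "corrected_truth", "background_level", "spot_level",
             "cx", "cy", "radius", "seed"]
        )
        cx, cy = spec.spot_center
        w.writerow(
            [path.name, truth, spec.background_level, spec.spot_level,
             cx, cy, spec.spot_radius_px, spec.seed]
        )
    return sidecar
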