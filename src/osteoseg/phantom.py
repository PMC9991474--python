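"""Synthetic trabecular-bone ROI phantoms and diagnosis labeling rules.

Real periapical radiographs paired with DEXA ground truth are rarely
distributable, so this module generates labeled stand-in textures with the
statistical structure the detection pipeline relies on: trabecular bone
rendered as a bright connected matrix and marrow pores as darker blobs,
with osteoporotic bone showing a higher pore fraction (reduced number and
size of trabeculae).

The texture model is a smoothed Gaussian random field: white noise is
convolved with a Gaussian kernel (``correlation_length`` sets the trabecular
scale), the field is thresholded at the ``porosity`` quantile to carve out
pores, pores are darkened by ``pore_darkness``, and radiographic quality is
emulated with a final Gaussian blur plus additive Gaussian noise.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from osteoseg.roi_io import ROI_HEIGHT, ROI_WIDTH, RoiImage, write_image

NONOSTEOPOROSIS = "nonosteoporosis"
OSTEOPOROSIS = "osteoporosis"

#: Mean intensity of the trabecular (bone) matrix before degradation.
TRABECULAR_LEVEL = 170.0

#: Default pore fractions for the two phantom classes.  Osteoporotic bone
#: has markedly higher porosity than non-osteoporotic bone.
POROSITY_NONOSTEO = 0.25
POROSITY_OSTEO = 0.45


def classify_tscore(t: float) -> str:
    """Map a DEXA T-score to {normal, osteopenia, osteoporosis}.

    WHO cut-offs: normal T >= -1.0; osteopenia -2.5 < T < -1.0;
    osteoporosis T <= -2.5.  Boundary values follow the closed bounds:
    T = -1.0 is normal, T = -2.5 is osteoporosis.
    """
    t = float(t)
    if not math.isfinite(t):
        raise ValueError(f"T-score must be finite, got {t!r}")
    if t >= -1.0:
        return "normal"
    if t <= -2.5:
        return "osteoporosis"
    return "osteopenia"


def to_binary_label(category: str) -> str:
    """Collapse the three densitometric categories to the binary diagnosis.

    Normal and osteopenia are pooled into the nonosteoporosis class;
    osteoporosis is the positive class.
    """
    if category == "osteoporosis":
        return OSTEOPOROSIS
    if category in ("normal", "osteopenia"):
        return NONOSTEOPOROSIS
    raise ValueError(f"unknown T-score category {category!r}")


@dataclass(frozen=True)
class PhantomParams:
    """Parameters of one synthetic trabecular ROI.

    Attributes
    ----------
    height, width:
        ROI geometry in pixels; the pipeline default is 300 x 400.
    correlation_length:
        Spatial scale (pixels) of the trabecular texture; the Gaussian
        smoothing radius applied to the white-noise field.
    porosity:
        Target fraction of pore pixels in [0, 1].
    pore_darkness:
        Intensity offset (0-255 units) subtracted inside pores.
    blur_sigma:
        Final Gaussian blur emulating detector/scatter blur.
    noise_sd:
        Standard deviation of additive Gaussian noise (intensity units).
    seed:
        Seed for the phantom's random field and noise.
    """

    height: int = ROI_HEIGHT
    width: int = ROI_WIDTH
    correlation_length: float = 3.0
    porosity: float = POROSITY_NONOSTEO
    pore_darkness: float = 60.0
    blur_sigma: float = 0.8
    noise_sd: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError(f"degenerate phantom dimensions {self.height}x{self.width}")
        if not 0.0 <= self.porosity <= 1.0:
            raise ValueError(f"porosity must lie in [0, 1], got {self.porosity}")
        if self.noise_sd < 0 or self.blur_sigma < 0:
            raise ValueError("noise_sd and blur_sigma must be nonnegative")
        if self.correlation_length <= 0:
            raise ValueError("correlation_length must be positive")

    @property
    def pore_threshold(self) -> float:
        """Intensity midpoint separating pore pixels from trabecular matrix."""
        return TRABECULAR_LEVEL - self.pore_darkness / 2.0


def _synthesize(params: PhantomParams) -> dict:
    """Run the generative stages; returns the pore mask and both the
    pre-noise and final images (float64, unclipped for intermediates)."""
    rng = np.random.default_rng(params.seed)
    field = rng.standard_normal((params.height, params.width))
    field = ndimage.gaussian_filter(field, sigma=params.correlation_length, mode="reflect")

    # Threshold the smoothed field at the porosity quantile: exactly the
    # target fraction of pixels (up to integer rounding) becomes pore.
    if params.porosity <= 0.0:
        pore_mask = np.zeros_like(field, dtype=bool)
    elif params.porosity >= 1.0:
        pore_mask = np.ones_like(field, dtype=bool)
    else:
        cut = np.quantile(field, params.porosity)
        pore_mask = field < cut

    image = np.full(field.shape, TRABECULAR_LEVEL, dtype=np.float64)
    image[pore_mask] -= params.pore_darkness
    if params.blur_sigma > 0:
        image = ndimage.gaussian_filter(image, sigma=params.blur_sigma, mode="reflect")
    pre_noise = image
    if params.noise_sd > 0:
        image = image + rng.normal(0.0, params.noise_sd, size=image.shape)
    final = np.clip(np.floor(image + 0.5), 0, 255)
    return {"pore_mask": pore_mask, "pre_noise": pre_noise, "final": final}


def generate_phantom(params: PhantomParams, source_id: str = "") -> RoiImage:
    """Generate one synthetic trabecular ROI; deterministic for a fixed seed."""
    stages = _synthesize(params)
    return RoiImage(stages["final"], source_id=source_id or f"phantom-{params.seed}")


def pore_fraction_pre_noise(params: PhantomParams) -> float:
    """Fraction of pre-noise pixels below the pore/trabecula midpoint.

    Diagnostic used to verify that the generator hits its porosity target
    before degradation noise is added.
    """
    stages = _synthesize(params)
    return float(np.mean(stages["pre_noise"] < params.pore_threshold))


def _image_seed(cohort_seed: int, class_index: int, index: int) -> int:
    """Deterministic per-image seed derived from (cohort seed, class, index)."""
    ss = np.random.SeedSequence([int(cohort_seed), class_index, index])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def class_params(label: str, base: PhantomParams | None = None) -> PhantomParams:
    """Default phantom parameters for a diagnosis class (porosity differs)."""
    base = base or PhantomParams()
    porosity = POROSITY_OSTEO if label == OSTEOPOROSIS else POROSITY_NONOSTEO
    return replace(base, porosity=porosity)


def cohort_params(
    n_per_class: int,
    params_nonosteo: PhantomParams | None = None,
    params_osteo: PhantomParams | None = None,
    seed: int = 0,
) -> list[tuple[str, PhantomParams, str]]:
    """Per-image (source_id, params, label) records for a balanced cohort.

    Per-image seeds derive deterministically from the cohort seed, the class,
    and the image index, so cohorts are reproducible and extensible.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    params_nonosteo = params_nonosteo or class_params(NONOSTEOPOROSIS)
    params_osteo = params_osteo or class_params(OSTEOPOROSIS)
    records = []
    for class_index, (label, base) in enumerate(
        [(NONOSTEOPOROSIS, params_nonosteo), (OSTEOPOROSIS, params_osteo)]
    ):
        for i in range(n_per_class):
            p = replace(base, seed=_image_seed(seed, class_index, i))
            records.append((f"{label}-{i:03d}", p, label))
    return records


def generate_cohort(
    n_per_class: int,
    params_nonosteo: PhantomParams | None = None,
    params_osteo: PhantomParams | None = None,
    seed: int = 0,
) -> list[tuple[RoiImage, str]]:
    """Generate a balanced labeled cohort of 2*n_per_class phantoms.

    Nonosteoporosis images come first, then osteoporosis.  Byte-identical
    for identical arguments.
    """
    return [
        (generate_phantom(p, source_id=sid), label)
        for sid, p, label in cohort_params(n_per_class, params_nonosteo, params_osteo, seed)
    ]


def generate_split(
    n_nonosteo: int,
    n_osteo: int,
    params_nonosteo: PhantomParams | None = None,
    params_osteo: PhantomParams | None = None,
    seed: int = 0,
    id_prefix: str = "",
) -> list[tuple[RoiImage, str]]:
    """Generate a possibly unbalanced labeled set (e.g. a 22+20 test split)."""
    params_nonosteo = params_nonosteo or class_params(NONOSTEOPOROSIS)
    params_osteo = params_osteo or class_params(OSTEOPOROSIS)
    out: list[tuple[RoiImage, str]] = []
    for class_index, (label, base, n) in enumerate(
        [(NONOSTEOPOROSIS, params_nonosteo, n_nonosteo), (OSTEOPOROSIS, params_osteo, n_osteo)]
    ):
        for i in range(n):
            p = replace(base, seed=_image_seed(seed, class_index, i))
            out.append((generate_phantom(p, source_id=f"{id_prefix}{label}-{i:03d}"), label))
    return out


def save_cohort(
    n_per_class: int,
    out_dir: str | Path,
    params_nonosteo: PhantomParams | None = None,
    params_osteo: PhantomParams | None = None,
    seed: int = 0,
    image_format: str = "png",
) -> Path:
    """Write cohort images plus a CSV manifest (filename, class, porosity, seed).

    Returns the manifest path.  ``image_format`` is ``png`` or ``bmp``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if image_format not in ("png", "bmp"):
        raise ValueError(f"unsupported image format {image_format!r}")
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "class", "porosity", "seed"])
        for sid, p, label in cohort_params(n_per_class, params_nonosteo, params_osteo, seed):
            fname = f"{sid}.{image_format}"
            write_image(generate_phantom(p, source_id=sid), out_dir / fname)
            writer.writerow([fname, label, p.porosity, p.seed])
    return manifest
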