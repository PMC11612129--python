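"""Synthetic speckle-phantom generator.

Emulates grayscale breast-ultrasound appearance well enough to exercise every
downstream stage with known ground truth: a multiplicative Rayleigh speckle
background containing one nodule whose BI-RADS descriptors (shape, margin,
orientation, echogenicity, posterior acoustic feature, echogenic halo) are
controlled and recorded, plus optional planted near-duplicates (rotated/zoomed
copies) for de-duplication tests.

The rendering vocabulary of cues:

* echogenicity — interior intensity relative to the background mean, ordered
  anechoic < hypoechoic < isoechoic (== background) < hyperechoic;
  "heterogeneous" is a patchwork of dark and bright blobs,
* shape — circle (round), ellipse (oval), low-frequency asymmetric boundary
  perturbation (irregular),
* margin — sharp edge (circumscribed), Gaussian-blurred edge (indistinct),
  regular high-frequency lobes (microlobulated), dark radial spikes
  (spiculated),
* orientation — whether the long axis runs parallel (wider than tall) or
  anti-parallel (taller than wide) to the skin line,
* posterior — the image column beneath the nodule brightened (enhancement) or
  darkened (shadowing),
* halo — a bright ring hugging the boundary.

Ground-truth boxes enclose the nodule, its spicules and halo, and the
posterior column, mirroring a detector trained to keep the context needed to
read the posterior feature.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

from .errors import ConfigurationError, GeometryError, InputError
from .roi_types import BoundingBox
from .vocab import (
    DEFAULT_VOCABULARIES,
    Vocabularies,
)

DEFAULT_CANVAS = (160, 160)  # (height, width)

#: Default sampling priors.  Suggestivity is drawn first; the special tumor
#: types then pin the descriptor pattern that defines them, so the type is
#: always recoverable from the visible descriptors.
DEFAULT_CLASS_WEIGHTS: dict[str, dict[str, float]] = {
    "suggestivity": {
        "simple_cyst": 0.14,
        "complex_cyst": 0.14,
        "fibroadenoma": 0.16,
        "no_clear_suggestivity": 0.56,
    },
    "shape": {"oval": 0.40, "round": 0.26, "irregular": 0.34},
    "margin": {
        "circumscribed": 0.34,
        "indistinct": 0.22,
        "microlobulated": 0.22,
        "spiculated": 0.22,
    },
    "orientation": {"parallel": 0.58, "anti_parallel": 0.42},  # non-round only
    "echogenicity": {
        "anechoic": 0.22,
        "hypoechoic": 0.26,
        "isoechoic": 0.16,
        "hyperechoic": 0.14,
        "heterogeneous": 0.22,
    },
    "posterior": {"none": 0.40, "enhancement": 0.34, "shadowing": 0.26},
    "halo": {"absent": 0.68, "present": 0.32},
}

# Interior intensity factors relative to the background mean.
_ECHO_FACTOR = {
    "anechoic": 0.07,
    "hypoechoic": 0.48,
    "isoechoic": 1.0,
    "hyperechoic": 1.75,
}


@dataclass(frozen=True)
class PhantomSpec:
    """Ground-truth description and geometry of one synthetic nodule."""

    shape: str
    margin: str
    orientation: str
    echogenicity: str
    posterior: str
    halo: str
    suggestivity: str
    malignant: bool
    center: tuple[float, float]  # (x, y) pixels
    semi_axes: tuple[float, float]  # (rx, ry) pixels
    rotation: float  # radians
    background_mean: float  # 0-255
    seed: int

    def __post_init__(self) -> None:
        v = DEFAULT_VOCABULARIES
        for name in ("shape", "margin", "orientation", "echogenicity",
                     "posterior", "halo", "suggestivity"):
            v.validate(name, getattr(self, name))
        if self.shape == "round":
            if self.orientation != "none":
                raise ConfigurationError("round nodules have no orientation")
            ratio = self.semi_axes[0] / self.semi_axes[1]
            if not 0.9 <= ratio <= 1.1:
                raise ConfigurationError(
                    f"round nodule semi-axis ratio {ratio:.3f} outside [0.9, 1.1]")
        if self.suggestivity == "simple_cyst":
            if (self.echogenicity, self.margin, self.posterior) != (
                    "anechoic", "circumscribed", "enhancement"):
                raise ConfigurationError(
                    "simple_cyst requires anechoic + circumscribed + enhancement")
        if self.margin == "spiculated" and not self.malignant:
            raise ConfigurationError("spiculated margin implies malignancy")

    def descriptors(self) -> dict[str, str]:
        """The seven categorical outputs, keyed by descriptor name."""
        return {
            "shape": self.shape,
            "margin": self.margin,
            "orientation": self.orientation,
            "echogenicity": self.echogenicity,
            "posterior": self.posterior,
            "halo": self.halo,
            "suggestivity": self.suggestivity,
        }


def classify_suggestivity(d: dict[str, str]) -> str:
    """Tumor type implied by the six visible descriptors (deterministic)."""
    if (d["echogenicity"], d["margin"], d["posterior"]) == (
            "anechoic", "circumscribed", "enhancement"):
        return "simple_cyst"
    if d["echogenicity"] == "heterogeneous" and d["posterior"] == "enhancement":
        return "complex_cyst"
    if (d["shape"], d["margin"], d["orientation"], d["echogenicity"]) == (
            "oval", "circumscribed", "parallel", "hypoechoic"):
        return "fibroadenoma"
    return "no_clear_suggestivity"


def derive_birads(spec: PhantomSpec | dict[str, str]) -> str:
    """Deterministic BI-RADS category for a descriptor combination.

    Hard rules first (simple cyst -> 2, spiculated -> 5, complex cyst -> 4A,
    spiculated dominating); otherwise monotone in the number of suspicious
    features among {irregular shape, microlobulated margin, anti-parallel
    orientation, posterior shadowing, halo present}:

    ========================  ========
    suspicious feature count  category
    ========================  ========
    0 (anechoic interior)       2
    0 (otherwise)               3
    1                           4A
    2                           4B
    3                           4C
    >= 4                        5
    ========================  ========
    """
    d = spec.descriptors() if isinstance(spec, PhantomSpec) else dict(spec)
    if d["margin"] == "spiculated":
        return "5"
    if d.get("suggestivity") == "simple_cyst":
        return "2"
    if d.get("suggestivity") == "complex_cyst":
        return "4A"
    suspicious = (
        (d["shape"] == "irregular")
        + (d["margin"] == "microlobulated")
        + (d["orientation"] == "anti_parallel")
        + (d["posterior"] == "shadowing")
        + (d["halo"] == "present")
    )
    if suspicious == 0:
        return "2" if d["echogenicity"] == "anechoic" else "3"
    return {1: "4A", 2: "4B", 3: "4C"}.get(suspicious, "5")


def is_malignant(category: str) -> bool:
    """Boolean malignancy induced by the category (4B and above)."""
    return category in ("4B", "4C", "5")


def _validate_weights(weights: dict[str, dict[str, float]],
                      vocab: Vocabularies) -> dict[str, dict[str, float]]:
    merged = {k: dict(v) for k, v in DEFAULT_CLASS_WEIGHTS.items()}
    for name, table in (weights or {}).items():
        if name not in merged:
            raise ConfigurationError(f"unknown descriptor in class_weights: {name!r}")
        merged[name] = dict(table)
    for name, table in merged.items():
        vals = np.array(list(table.values()), dtype=float)
        if (vals < 0).any():
            raise ConfigurationError(f"negative weight for descriptor {name!r}")
        if abs(vals.sum() - 1.0) > 1e-6:
            raise ConfigurationError(
                f"class_weights for {name!r} sum to {vals.sum():.4f}, not 1")
    return merged


def _choice(rng: np.random.Generator, table: dict[str, float]) -> str:
    keys = list(table)
    p = np.array([table[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=p / p.sum())]


def sample_phantom_spec(
    rng_seed: int,
    class_weights: dict[str, dict[str, float]] | None = None,
    canvas: tuple[int, int] = DEFAULT_CANVAS,
    vocab: Vocabularies = DEFAULT_VOCABULARIES,
) -> PhantomSpec:
    """Draw one nodule specification satisfying every invariant.

    The tumor type (suggestivity) is drawn first; special types pin the
    descriptor pattern that defines them, and free combinations that would
    collide with a special pattern are nudged off it, so
    :func:`classify_suggestivity` always round-trips.
    """
    weights = _validate_weights(class_weights or {}, vocab)
    rng = np.random.default_rng(rng_seed)
    h, w = canvas

    sugg = _choice(rng, weights["suggestivity"])
    d: dict[str, str] = {}
    if sugg == "simple_cyst":
        d["echogenicity"], d["margin"], d["posterior"] = (
            "anechoic", "circumscribed", "enhancement")
        d["shape"] = "round" if rng.random() < 0.5 else "oval"
        d["halo"] = "absent"
    elif sugg == "complex_cyst":
        d["echogenicity"], d["posterior"] = "heterogeneous", "enhancement"
        d["margin"] = _choice(rng, {"circumscribed": 0.5, "indistinct": 0.25,
                                    "microlobulated": 0.25})
        d["shape"] = _choice(rng, weights["shape"])
        d["halo"] = _choice(rng, weights["halo"])
    elif sugg == "fibroadenoma":
        d["shape"], d["margin"], d["echogenicity"] = "oval", "circumscribed", "hypoechoic"
        d["posterior"] = _choice(rng, {"none": 0.6, "shadowing": 0.4})
        d["halo"] = "absent"
    else:
        d["shape"] = _choice(rng, weights["shape"])
        d["margin"] = _choice(rng, weights["margin"])
        d["echogenicity"] = _choice(rng, weights["echogenicity"])
        d["posterior"] = _choice(rng, weights["posterior"])
        d["halo"] = _choice(rng, weights["halo"])

    if d["shape"] == "round":
        d["orientation"] = "none"
    elif sugg == "fibroadenoma":
        d["orientation"] = "parallel"
    else:
        d["orientation"] = _choice(rng, weights["orientation"])

    # Nudge free draws off special patterns so the type label stays consistent.
    if sugg == "no_clear_suggestivity":
        while classify_suggestivity(d) != "no_clear_suggestivity":
            implied = classify_suggestivity(d)
            if implied in ("simple_cyst", "complex_cyst"):
                d["posterior"] = "none"
            else:  # fibroadenoma pattern
                d["echogenicity"] = "isoechoic"

    # Geometry.  r0 is the geometric-mean radius; the long axis follows the
    # orientation (parallel: wider than tall).
    r0 = rng.uniform(0.10, 0.15) * min(h, w)
    if d["shape"] == "round":
        ratio = rng.uniform(0.92, 1.08)
        rx, ry = r0 * math.sqrt(ratio), r0 / math.sqrt(ratio)
    else:
        aspect = rng.uniform(1.5, 2.0) if d["shape"] == "oval" else rng.uniform(1.2, 1.5)
        if d["orientation"] == "parallel":
            rx, ry = r0 * math.sqrt(aspect), r0 / math.sqrt(aspect)
        else:
            rx, ry = r0 / math.sqrt(aspect), r0 * math.sqrt(aspect)
    rotation = rng.uniform(-0.1, 0.1)

    pad = 0.62 * r0 + 5.0  # room for spicules and halo
    cx = rng.uniform(rx + pad, w - rx - pad)
    cy = rng.uniform(ry + pad, 0.42 * h)

    birads = derive_birads({**d, "suggestivity": sugg})
    return PhantomSpec(
        shape=d["shape"], margin=d["margin"], orientation=d["orientation"],
        echogenicity=d["echogenicity"], posterior=d["posterior"], halo=d["halo"],
        suggestivity=sugg, malignant=is_malignant(birads),
        center=(round(cx, 3), round(cy, 3)),
        semi_axes=(round(rx, 3), round(ry, 3)),
        rotation=round(rotation, 4),
        background_mean=round(rng.uniform(100.0, 130.0), 2),
        seed=int(rng.integers(0, 2**31)),
    )


def _boundary_scale(theta: np.ndarray, spec: PhantomSpec,
                    rng: np.random.Generator) -> np.ndarray:
    """Angular radius modulation implementing the margin treatment."""
    scale = np.ones_like(theta)
    if spec.margin == "microlobulated":
        # fine, regular scalloping: high frequency, moderate amplitude,
        # a different frequency band from the multi-lobed irregular form
        n_lobes = int(rng.integers(12, 17))
        scale += 0.13 * np.sin(n_lobes * theta + rng.uniform(0, 2 * np.pi))
    return scale


def _radial_field(xr: np.ndarray, yr: np.ndarray, rx: float, ry: float,
                  spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Normalized radial coordinate of the nodule body (1 = boundary).

    Oval and round bodies are single ellipses.  An irregular body is the
    union of the main ellipse with two or three overlapping satellite
    ellipses — a multi-lobed composite no margin treatment can imitate,
    keeping the shape and margin cues orthogonal.
    """
    rho = np.sqrt((xr / rx) ** 2 + (yr / ry) ** 2)
    if spec.shape != "irregular":
        return rho
    r0 = math.sqrt(rx * ry)
    # protruding lobes (at least one far enough out to break the ellipse)
    n_sat = int(rng.integers(2, 4))
    dists = rng.uniform(0.55, 0.8, n_sat)
    dists[0] = rng.uniform(0.7, 0.82)
    for dist_frac in dists:
        ang = rng.uniform(0, 2 * np.pi)
        dist = dist_frac * r0
        ox, oy = dist * math.cos(ang), dist * math.sin(ang)
        srx = rng.uniform(0.5, 0.65) * rx
        sry = rng.uniform(0.5, 0.65) * ry
        rho_sat = np.sqrt(((xr - ox) / srx) ** 2 + ((yr - oy) / sry) ** 2)
        rho = np.minimum(rho, rho_sat)
    # one concave notch bitten out of the main boundary: ellipses (with or
    # without scalloped margins) are never concave, so concavity alone
    # separates the irregular form
    ang = rng.uniform(0, 2 * np.pi)
    ox, oy = 1.08 * rx * math.cos(ang), 1.08 * ry * math.sin(ang)
    nr = rng.uniform(0.40, 0.55)
    rho_notch = np.sqrt(((xr - ox) / (nr * rx)) ** 2 + ((yr - oy) / (nr * ry)) ** 2)
    rho = np.maximum(rho, 2.0 - rho_notch)
    return rho


def render_phantom(
    spec: PhantomSpec,
    canvas: tuple[int, int] = DEFAULT_CANVAS,
) -> tuple[np.ndarray, BoundingBox]:
    """Render one nodule onto a speckle background.

    Returns the 8-bit grayscale image and the tight ground-truth box covering
    nodule, spicules, halo and the posterior column.  Rendering is a pure
    function of ``(spec, canvas)``: every random draw comes from
    ``spec.seed``.
    """
    h, w = canvas
    cx, cy = spec.center
    rx, ry = spec.semi_axes
    if not (rx > 0 and ry > 0):
        raise GeometryError("semi-axes must be positive")
    if cx - rx < 0 or cx + rx > w or cy - ry < 0 or cy + ry > h:
        raise GeometryError("nodule does not fit inside the canvas")
    rng = np.random.default_rng(spec.seed)

    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    dx, dy = xx - cx, yy - cy
    cos_t, sin_t = math.cos(spec.rotation), math.sin(spec.rotation)
    xr = dx * cos_t + dy * sin_t
    yr = -dx * sin_t + dy * cos_t
    rho = _radial_field(xr, yr, rx, ry, spec, rng)
    theta = np.arctan2(yr / ry, xr / rx)

    scale = _boundary_scale(theta, spec, rng)
    mask = rho <= scale

    # --- interior intensity -------------------------------------------------
    factor = np.ones((h, w), dtype=np.float64)
    if spec.echogenicity == "heterogeneous":
        field = gaussian_filter(rng.standard_normal((h, w)), 2.5)
        interior = np.where(field > 0, 1.30, 0.22)
        factor[mask] = interior[mask]
    else:
        factor[mask] = _ECHO_FACTOR[spec.echogenicity]

    # Thin dark rim so isoechoic nodules remain visible; blurred away for
    # indistinct margins.
    rim = (rho > scale - 0.10) & (rho <= scale + 0.05)
    factor[rim] *= 0.50

    if spec.halo == "present":
        ring = (rho > scale + 0.04) & (rho <= scale + 0.30)
        factor[ring] = 1.85

    if spec.margin == "spiculated":
        n_spikes = int(rng.integers(9, 14))
        angles = np.sort(rng.uniform(0, 2 * np.pi, n_spikes))
        widths = rng.uniform(0.05, 0.09, n_spikes)
        lengths = rng.uniform(0.45, 0.65, n_spikes)
        spike = np.zeros((h, w), dtype=bool)
        for a, wdt, ln in zip(angles, widths, lengths):
            ang = np.abs((theta - a + np.pi) % (2 * np.pi) - np.pi)
            spike |= (ang < wdt) & (rho > scale) & (rho <= scale + ln)
        factor[spike] = 0.30

    if spec.margin == "indistinct":
        factor = gaussian_filter(factor, 3.2)

    # --- posterior column ---------------------------------------------------
    nod_bottom = cy + ry * 1.12
    post_len = 1.7 * ry
    col = np.zeros((h, w), dtype=np.float64)
    col_x = (np.abs(dx) <= 0.8 * rx)
    col_y = (yy >= nod_bottom) & (yy <= min(h, nod_bottom + post_len))
    col[col_x & col_y & ~mask] = 1.0
    col = gaussian_filter(col, 1.0)
    if spec.posterior == "enhancement":
        factor *= 1.0 + 0.65 * col
    elif spec.posterior == "shadowing":
        factor *= 1.0 - 0.68 * col

    base = spec.background_mean * factor

    # --- multiplicative correlated Rayleigh speckle -------------------------
    speckle = rng.rayleigh(scale=1.0, size=(h, w)) / math.sqrt(math.pi / 2.0)
    speckle = gaussian_filter(speckle, 0.7)
    img = np.clip(base * speckle, 0, 255).astype(np.uint8)

    # --- tight ground-truth box ---------------------------------------------
    ext = mask | (rho <= scale + (0.34 if spec.halo == "present" else 0.0))
    if spec.margin == "spiculated":
        ext |= rho <= scale + 0.65
    cols = np.where(ext.any(axis=0))[0]
    rows = np.where(ext.any(axis=1))[0]
    x0, x1 = int(cols[0]), int(cols[-1]) + 1
    y0 = int(rows[0])
    y1 = min(h, int(math.ceil(nod_bottom + post_len)))
    y1 = max(y1, int(rows[-1]) + 1)
    box = BoundingBox(x0=x0, y0=y0, x1=x1, y1=y1, confidence=1.0).clipped(w, h)
    return img, box


# ---------------------------------------------------------------------------
# Dataset emission
# ---------------------------------------------------------------------------

_EXTRA_INFO_FRACTION = 0.1


def _stamp_extra_info(img: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Burn a bright annotation block into a corner (a 'Clever Hans' cue)."""
    out = img.copy()
    s = 10
    out[2:2 + s, -2 - s:-2] = 250
    out[4 + s:6 + s, -2 - 2 * s:-2] = 240
    return out


def _record_to_json(rec: dict) -> dict:
    rec = dict(rec)
    rec["spec"] = asdict(rec["spec"]) if isinstance(rec["spec"], PhantomSpec) else rec["spec"]
    return rec


def spec_from_dict(d: dict) -> PhantomSpec:
    d = dict(d)
    d["center"] = tuple(d["center"])
    d["semi_axes"] = tuple(d["semi_axes"])
    return PhantomSpec(**d)


def write_box_file(path: Path, box: BoundingBox, canvas: tuple[int, int]) -> None:
    """One-stage-detector dialect: 'class cx cy w h' normalized to [0, 1]."""
    h, w = canvas
    cx = (box.x0 + box.x1) / 2.0 / w
    cy = (box.y0 + box.y1) / 2.0 / h
    bw = (box.x1 - box.x0) / w
    bh = (box.y1 - box.y0) / h
    path.write_text(f"0 {cx:.6f} {cy:.6f} {bw:.6f} {bh:.6f}\n")


def read_box_file(path: Path, canvas: tuple[int, int]) -> BoundingBox:
    h, w = canvas
    parts = Path(path).read_text().split()
    cx, cy, bw, bh = (float(p) for p in parts[1:5])
    x0 = int(round((cx - bw / 2) * w))
    y0 = int(round((cy - bh / 2) * h))
    x1 = int(round((cx + bw / 2) * w))
    y1 = int(round((cy + bh / 2) * h))
    return BoundingBox(x0=x0, y0=y0, x1=x1, y1=y1, confidence=1.0).clipped(w, h)


def make_dataset(
    n: int,
    seed: int,
    out_dir: str | Path,
    class_weights: dict[str, dict[str, float]] | None = None,
    canvas: tuple[int, int] = DEFAULT_CANVAS,
    extra_info_fraction: float = _EXTRA_INFO_FRACTION,
) -> dict:
    """Write ``n`` phantoms with boxes, a label table and a JSON manifest.

    Images flagged ``extra_info`` carry a burned-in annotation block; split
    helpers keep them out of validation/test folds.
    """
    if n < 1:
        raise InputError("n must be >= 1")
    out_dir = Path(out_dir)
    try:
        (out_dir / "images").mkdir(parents=True, exist_ok=True)
        (out_dir / "boxes").mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover - environment dependent
        raise InputError(f"cannot create output directory {out_dir}: {exc}") from exc

    rng = np.random.default_rng(seed)
    spec_seeds = rng.integers(0, 2**31, size=n)
    extra = rng.random(n) < extra_info_fraction

    records = []
    for i in range(n):
        image_id = f"img_{i:05d}"
        spec = sample_phantom_spec(int(spec_seeds[i]), class_weights, canvas)
        img, box = render_phantom(spec, canvas)
        if extra[i]:
            img = _stamp_extra_info(img, np.random.default_rng(spec.seed + 1))
        Image.fromarray(img).save(out_dir / "images" / f"{image_id}.png")
        write_box_file(out_dir / "boxes" / f"{image_id}.txt", box, canvas)
        records.append({
            "image_id": image_id,
            "image": f"images/{image_id}.png",
            "box_file": f"boxes/{image_id}.txt",
            "box": [box.x0, box.y0, box.x1, box.y1],
            "spec": spec,
            "birads": derive_birads(spec),
            "malignant": spec.malignant,
            "extra_info": bool(extra[i]),
            "duplicate_of": None,
        })

    manifest = {
        "n": n,
        "seed": seed,
        "canvas": list(canvas),
        "root": str(out_dir),
        "records": [_record_to_json(r) for r in records],
    }
    _write_labels(out_dir, manifest)
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _write_labels(out_dir: Path, manifest: dict) -> None:
    import pandas as pd

    rows = []
    for r in manifest["records"]:
        spec = r["spec"]
        rows.append({
            "image_id": r["image_id"],
            **{k: spec[k] for k in ("shape", "margin", "orientation",
                                    "echogenicity", "posterior", "halo",
                                    "suggestivity")},
            "malignant": r["malignant"],
            "birads": r["birads"],
            "extra_info": r["extra_info"],
        })
    pd.DataFrame(rows).to_csv(out_dir / "labels.csv", index=False)


def manifest_checksum(manifest: dict) -> str:
    """Stable digest of a manifest's content (order-insensitive keys)."""
    payload = json.dumps(manifest, sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()


def load_manifest(path: str | Path) -> dict:
    path = Path(path)
    manifest = json.loads(path.read_text())
    manifest["root"] = str(path.parent)
    return manifest


def load_image(manifest: dict, record: dict) -> np.ndarray:
    return np.asarray(Image.open(Path(manifest["root"]) / record["image"]))


def make_duplicates(
    manifest: dict,
    n_pairs: int,
    rotation_max: float = 15.0,
    zoom_range: tuple[float, float] = (0.8, 1.2),
    conflict_fraction: float = 0.0,
    seed: int = 0,
) -> dict:
    """Plant rotated/zoomed near-duplicate copies into an existing dataset.

    The first ``floor(conflict_fraction * n_pairs)`` copies get a flipped
    malignancy label, emulating cross-class duplicates found in public
    datasets.  Provenance (source id, rotation, zoom) is recorded under
    ``duplicate_of``.
    """
    from skimage.transform import AffineTransform, warp

    originals = [r for r in manifest["records"] if r["duplicate_of"] is None]
    if not originals:
        raise InputError("manifest contains no images")
    if n_pairs > len(originals):
        raise InputError("n_pairs exceeds number of images in manifest")
    rng = np.random.default_rng(seed)
    sources = [originals[i] for i in
               rng.choice(len(originals), size=n_pairs, replace=False)]
    n_conflict = int(math.floor(conflict_fraction * n_pairs))
    out_dir = Path(manifest["root"])
    h, w = manifest["canvas"]

    new_records = []
    for j, src in enumerate(sources):
        image_id = f"dup_{j:05d}"
        angle = float(rng.uniform(-rotation_max, rotation_max))
        zoom = float(rng.uniform(*zoom_range))
        img = load_image(manifest, src).astype(np.float64)
        centre = np.array([w, h]) / 2.0
        tf = (AffineTransform(translation=centre)
              + AffineTransform(rotation=np.deg2rad(angle), scale=zoom)
              + AffineTransform(translation=-centre))
        warped = warp(img, tf.inverse, mode="reflect", preserve_range=True)
        warped = np.clip(warped, 0, 255).astype(np.uint8)
        Image.fromarray(warped).save(out_dir / "images" / f"{image_id}.png")

        corners = np.array([[src["box"][0], src["box"][1]],
                            [src["box"][2], src["box"][1]],
                            [src["box"][0], src["box"][3]],
                            [src["box"][2], src["box"][3]]], dtype=float)
        warped_corners = tf(corners)
        x0, y0 = warped_corners.min(axis=0)
        x1, y1 = warped_corners.max(axis=0)
        box = BoundingBox(int(max(0, x0)), int(max(0, y0)),
                          int(min(w, x1)), int(min(h, y1)), 1.0)
        write_box_file(out_dir / "boxes" / f"{image_id}.txt", box, (h, w))

        conflicted = j < n_conflict
        rec = {
            "image_id": image_id,
            "image": f"images/{image_id}.png",
            "box_file": f"boxes/{image_id}.txt",
            "box": [box.x0, box.y0, box.x1, box.y1],
            "spec": dict(src["spec"] if isinstance(src["spec"], dict)
                         else asdict(src["spec"])),
            "birads": src["birads"],
            "malignant": (not src["malignant"]) if conflicted else src["malignant"],
            "extra_info": False,
            "duplicate_of": {
                "image_id": src["image_id"],
                "rotation_deg": round(angle, 3),
                "zoom": round(zoom, 4),
                "label_conflict": conflicted,
            },
        }
        new_records.append(rec)

    manifest = dict(manifest)
    manifest["records"] = list(manifest["records"]) + new_records
    _write_labels(out_dir, manifest)
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def split_folds(manifest: dict, k: int, seed: int = 0) -> list[dict[str, list[str]]]:
    """K-fold splits; extra_info images train everywhere, validate nowhere."""
    if k < 2:
        raise ConfigurationError("k must be >= 2")
    ids = [r["image_id"] for r in manifest["records"]]
    eligible = [r["image_id"] for r in manifest["records"] if not r["extra_info"]]
    always_train = [i for i in ids if i not in set(eligible)]
    rng = np.random.default_rng(seed)
    order = [eligible[i] for i in rng.permutation(len(eligible))]
    folds = [order[i::k] for i in range(k)]
    out = []
    for i in range(k):
        val = folds[i]
        train = [x for x in order if x not in set(val)] + always_train
        out.append({"train": train, "val": val})
    return out
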