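"""Synthetic ovarian-ultrasound phantoms with exact ground truth.

Each phantom emulates the appearance hierarchy of a B-mode ovary image: an
echogenic speckled background, one darker (hypoechoic) elliptical ovary, and
0-12 near-black (anechoic) elliptical follicles lying entirely inside the
ovary, at a known mm-per-pixel scale.  Speckle is the standard
fully-developed-speckle approximation: the squared magnitude of low-pass
filtered complex Gaussian noise, applied multiplicatively to a smooth
echogenicity field.  Optional artifacts (a vertical shadow band, global
contrast reduction) mimic the degradations common in transvaginal scans.

Every scene is fully determined by its seed and carries exact masks plus the
true per-follicle diameter (mean of the two axis lengths times the pixel
spacing).  Sampled diameters avoid a small guard band around the 2 and 10 mm
recruitable bounds so that the ground-truth antral count is unambiguous under
the <= 1 px error of moment-based diameter measurement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation, binary_erosion, gaussian_filter

from .quantify import RECRUITABLE_HIGH_MM, RECRUITABLE_LOW_MM

DEFAULT_SIZE_PX = 384
DEFAULT_SPACING_MM = 0.1
DEFAULT_DIAMETER_RANGE_MM = (2.0, 28.0)
BOUNDARY_GUARD_MM = 0.3


@dataclass(frozen=True)
class FolliclePhantom:
    center: tuple[float, float]        # (row, col), pixels
    semi_axes_px: tuple[float, float]  # (major, minor) semi-axes
    orientation: float                 # radians
    diameter_mm: float                 # spacing * (semi_major + semi_minor)

    @property
    def recruitable(self) -> bool:
        return RECRUITABLE_LOW_MM <= self.diameter_mm <= RECRUITABLE_HIGH_MM


@dataclass
class PhantomScene:
    image: np.ndarray                 # float64 in [0, 1]
    ovary_mask: np.ndarray            # uint8 {0, 1}
    follicle_mask: np.ndarray         # uint8 {0, 1}
    follicles: list[FolliclePhantom]
    pixel_spacing_mm: float
    seed: int
    params: dict = field(default_factory=dict)

    @property
    def true_antral_count(self) -> int:
        return sum(f.recruitable for f in self.follicles)


def _ellipse_mask(shape: tuple[int, int], center: tuple[float, float],
                  semi_axes: tuple[float, float], theta: float) -> np.ndarray:
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]].astype(np.float64)
    dr = rr - center[0]
    dc = cc - center[1]
    # rotate into the ellipse frame
    u = dr * np.cos(theta) + dc * np.sin(theta)
    v = -dr * np.sin(theta) + dc * np.cos(theta)
    a, b = semi_axes
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _guarded_diameter(rng: np.random.Generator, low: float, high: float,
                      guard: float) -> float:
    """Log-uniform diameter in [low, high], avoiding the recruitable bounds."""
    for _ in range(200):
        d = float(np.exp(rng.uniform(np.log(low), np.log(high))))
        near_bound = any(
            abs(d - bound) < guard
            for bound in (RECRUITABLE_LOW_MM, RECRUITABLE_HIGH_MM)
        )
        if not near_bound:
            return d
    raise RuntimeError("could not sample a diameter outside the guard bands")


def generate_phantom(n_follicles: int,
                     diameter_range_mm: tuple[float, float] = DEFAULT_DIAMETER_RANGE_MM,
                     size_px: int = DEFAULT_SIZE_PX,
                     spacing_mm: float = DEFAULT_SPACING_MM,
                     speckle_params: dict | None = None,
                     shadow: bool = False,
                     contrast: float = 1.0,
                     seed: int = 0,
                     min_separation_px: int = 2,
                     max_attempts: int = 200) -> PhantomScene:
    """Generate one seeded phantom scene with exact ground truth.

    Parameters
    ----------
    n_follicles:
        Number of follicles to place (all inside the ovary, pairwise
        separated by at least ``min_separation_px``).
    diameter_range_mm:
        Requested range of true diameters; per-follicle samples are truncated
        to what fits inside the sampled ovary.
    speckle_params:
        Optional dict with keys ``sigma`` (low-pass width of the complex
        noise, default 1.2 px) and ``strength`` (mixing weight in [0, 1] of
        the speckle against the smooth field, default 1.0).
    shadow:
        Add a vertical attenuation band (acoustic shadow artifact).
    contrast:
        Multiplier < 1 compresses the intensity hierarchy (poor-contrast
        artifact).

    Raises
    ------
    RuntimeError
        If the requested follicles cannot be packed into the ovary after
        ``max_attempts`` rejections each.
    """
    if n_follicles < 0:
        raise ValueError("n_follicles must be >= 0")
    rng = np.random.default_rng(seed)
    shape = (size_px, size_px)

    # hypoechoic ovary: one ellipse roughly centred in the field of view
    center = (size_px * (0.5 + rng.uniform(-0.04, 0.04)),
              size_px * (0.5 + rng.uniform(-0.04, 0.04)))
    ov_a = size_px * rng.uniform(0.30, 0.40)
    ov_b = size_px * rng.uniform(0.22, 0.32)
    ov_theta = rng.uniform(0.0, np.pi)
    ovary = _ellipse_mask(shape, center, (ov_a, ov_b), ov_theta)
    allowed = binary_erosion(ovary, iterations=max(2, min_separation_px))

    low, high = diameter_range_mm
    # a follicle cannot be larger than what fits inside the ovary
    feasible_high = min(high, 0.8 * 2.0 * ov_b * spacing_mm)
    if feasible_high <= low and n_follicles > 0:
        raise RuntimeError(
            f"requested diameters ({low}-{high} mm) infeasible inside a "
            f"{2 * ov_b * spacing_mm:.1f} mm ovary"
        )

    follicle_mask = np.zeros(shape, dtype=bool)
    follicles: list[FolliclePhantom] = []
    sep = np.ones((2 * min_separation_px + 1,) * 2, dtype=bool)
    for _ in range(n_follicles):
        placed = False
        for _attempt in range(max_attempts):
            d = _guarded_diameter(rng, low, feasible_high, BOUNDARY_GUARD_MM)
            q = rng.uniform(0.6, 1.0)            # minor/major aspect
            sa = d / (spacing_mm * (1.0 + q))    # semi-major, px
            sb = q * sa
            theta = rng.uniform(0.0, np.pi)
            fc = (rng.uniform(center[0] - ov_b, center[0] + ov_b),
                  rng.uniform(center[1] - ov_a, center[1] + ov_a))
            cand = _ellipse_mask(shape, fc, (sa, sb), theta)
            if not cand.any() or not allowed[cand].all():
                continue
            if binary_dilation(cand, structure=sep)[follicle_mask].any():
                continue
            follicle_mask |= cand
            follicles.append(FolliclePhantom(
                center=fc, semi_axes_px=(sa, sb), orientation=theta,
                diameter_mm=spacing_mm * (sa + sb),
            ))
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place follicle {len(follicles) + 1} of "
                f"{n_follicles} after {max_attempts} attempts"
            )

    sp = {"sigma": 1.2, "strength": 1.0}
    sp.update(speckle_params or {})

    # smooth echogenicity field with the anechoic < hypoechoic < background order
    base = 0.62 + 0.08 * _smooth_noise(rng, shape, sigma=size_px / 8.0)
    tissue = base.copy()
    tissue[ovary] *= 0.45
    tissue[follicle_mask] = 0.04
    speckle = _speckle_field(rng, shape, sigma=sp["sigma"])
    image = tissue * ((1.0 - sp["strength"]) + sp["strength"] * speckle)
    if shadow:
        c0 = int(rng.uniform(0.1, 0.7) * size_px)
        width = int(rng.uniform(0.08, 0.18) * size_px)
        image[:, c0:c0 + width] *= 0.5
    if contrast != 1.0:
        image = 0.5 + contrast * (image - 0.5)
    image = np.clip(image, 0.0, 1.0)

    return PhantomScene(
        image=image,
        ovary_mask=ovary.astype(np.uint8),
        follicle_mask=follicle_mask.astype(np.uint8),
        follicles=follicles,
        pixel_spacing_mm=spacing_mm,
        seed=int(seed),
        params={"size_px": size_px, "spacing_mm": spacing_mm,
                "diameter_range_mm": list(diameter_range_mm),
                "shadow": bool(shadow), "contrast": contrast,
                "speckle": sp, "n_follicles": n_follicles},
    )


def _smooth_noise(rng, shape, sigma):
    z = gaussian_filter(rng.standard_normal(shape), sigma)
    z_std = z.std()
    return z / z_std if z_std > 0 else z


def _speckle_field(rng, shape, sigma):
    """Squared magnitude of low-pass complex Gaussian noise, unit mean."""
    re = gaussian_filter(rng.standard_normal(shape), sigma)
    im = gaussian_filter(rng.standard_normal(shape), sigma)
    s = re * re + im * im
    return s / s.mean()


def sample_scene(rng: np.random.Generator,
                 size_px: int = 96,
                 spacing_mm: float = 0.4,
                 n_follicles_range: tuple[int, int] = (0, 6),
                 diameter_range_mm: tuple[float, float] = (2.0, 14.0),
                 shadow_prob: float = 0.3,
                 low_contrast_prob: float = 0.3) -> PhantomScene:
    """Draw one scene with randomized follicle count and artifacts.

    Defaults are the desk-scale study conditions: 96 px at 0.4 mm/px keeps
    the 38.4 mm field of view of the full-scale 384 px / 0.1 mm configuration.
    """
    for _ in range(50):
        seed = int(rng.integers(0, 2 ** 31 - 1))
        n = int(rng.integers(n_follicles_range[0], n_follicles_range[1] + 1))
        shadow = bool(rng.random() < shadow_prob)
        contrast = (float(rng.uniform(0.6, 0.9))
                    if rng.random() < low_contrast_prob else 1.0)
        try:
            return generate_phantom(
                n_follicles=n, diameter_range_mm=diameter_range_mm,
                size_px=size_px, spacing_mm=spacing_mm, shadow=shadow,
                contrast=contrast, seed=seed,
            )
        except RuntimeError:
            continue  # crowded draw was infeasible; redraw count and layout
    raise RuntimeError("could not sample a feasible scene in 50 draws")


def generate_dataset(n_images: int, out_dir: str | Path,
                     split_fractions: tuple[float, ...] = (0.6, 0.2, 0.2),
                     seed: int = 0,
                     size_px: int = DEFAULT_SIZE_PX,
                     spacing_mm: float = DEFAULT_SPACING_MM,
                     n_follicles_range: tuple[int, int] = (0, 12),
                     diameter_range_mm: tuple[float, float] = DEFAULT_DIAMETER_RANGE_MM,
                     ) -> pd.DataFrame:
    """Write a phantom dataset (PNG images + masks) with a regeneration manifest.

    Splits are named train/val/test (extra fractions get split3, ...); counts
    are floor(fraction * n) with the remainder assigned to the first split.
    Returns the manifest as a DataFrame; also writes manifest.csv (one row per
    image) and manifest.json (per-image follicle tables).
    """
    import imageio.v3 as iio

    if abs(sum(split_fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    if n_images < len(split_fractions):
        raise ValueError("need at least one image per split")
    out_dir = Path(out_dir)
    names = ["train", "val", "test"] + [
        f"split{i}" for i in range(3, len(split_fractions))
    ]
    names = names[: len(split_fractions)]
    counts = [int(np.floor(fr * n_images)) for fr in split_fractions]
    counts[0] += n_images - sum(counts)
    split_of = np.repeat(names, counts)

    master = np.random.SeedSequence(seed)
    rows = []
    follicle_tables = {}
    rng = np.random.default_rng(master)
    for i in range(n_images):
        n = int(rng.integers(n_follicles_range[0], n_follicles_range[1] + 1))
        scene = None
        for attempt in range(50):
            scene_seed = int(
                np.random.SeedSequence([seed, i, attempt]).generate_state(1)[0]
                % (2 ** 31 - 1)
            )
            try:
                scene = generate_phantom(
                    n_follicles=n, diameter_range_mm=diameter_range_mm,
                    size_px=size_px, spacing_mm=spacing_mm, seed=scene_seed,
                )
                break
            except RuntimeError:
                n = max(n_follicles_range[0], n - 1)  # relax the crowding
        if scene is None:
            raise RuntimeError(f"could not generate image {i} in 50 attempts")
        split = split_of[i]
        name = f"phantom_{i:04d}"
        for sub, arr in (
            ("images", (scene.image * 255).round().astype(np.uint8)),
            ("ovary_masks", scene.ovary_mask * 255),
            ("follicle_masks", scene.follicle_mask * 255),
        ):
            p = out_dir / split / sub
            p.mkdir(parents=True, exist_ok=True)
            iio.imwrite(p / f"{name}.png", arr)
        rows.append({
            "name": name, "split": split, "seed": scene_seed,
            "size_px": size_px, "spacing_mm": spacing_mm,
            "n_follicles": len(scene.follicles),
            "n_antral": scene.true_antral_count,
        })
        follicle_tables[name] = [
            {"center_row": f.center[0], "center_col": f.center[1],
             "semi_major_px": f.semi_axes_px[0],
             "semi_minor_px": f.semi_axes_px[1],
             "orientation_rad": f.orientation,
             "diameter_mm": f.diameter_mm}
            for f in scene.follicles
        ]
    manifest = pd.DataFrame(rows)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    manifest.attrs["diameter_range_mm"] = diameter_range_mm
    (out_dir / "manifest.json").write_text(json.dumps({
        "seed": seed, "n_images": n_images,
        "split_fractions": list(split_fractions),
        "size_px": size_px, "spacing_mm": spacing_mm,
        "n_follicles_range": list(n_follicles_range),
        "diameter_range_mm": list(diameter_range_mm),
        "images": rows, "follicles": follicle_tables,
    }, indent=2))
    return manifest


def regenerate_from_manifest(manifest_json: str | Path,
                             out_dir: str | Path) -> None:
    """Rebuild a dataset bit-identically from its manifest.json."""
    import imageio.v3 as iio

    meta = json.loads(Path(manifest_json).read_text())
    out_dir = Path(out_dir)
    for row in meta["images"]:
        scene = generate_phantom(
            n_follicles=row["n_follicles"],
            diameter_range_mm=tuple(meta["diameter_range_mm"]),
            size_px=row["size_px"], spacing_mm=row["spacing_mm"],
            seed=row["seed"],
        )
        for sub, arr in (
            ("images", (scene.image * 255).round().astype(np.uint8)),
            ("ovary_masks", scene.ovary_mask * 255),
            ("follicle_masks", scene.follicle_mask * 255),
        ):
            p = out_dir / row["split"] / sub
            p.mkdir(parents=True, exist_ok=True)
            iio.imwrite(p / f"{row['name']}.png", arr)
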