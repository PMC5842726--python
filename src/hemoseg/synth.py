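"""Seeded synthetic blood-smear generator with instance-level ground truth.

Emulates the appearance a brightfield camera sees on a Wright-Giemsa stained
smear: a bright near-uniform background, many disc-like erythrocytes with a
paler biconcave centre that may touch and overlap, fewer and larger
leukocytes carrying a dark purple lobed nucleus inside lighter cytoplasm,
small dark platelets, global stain-colour variation and mild sensor noise.
Geometry is exact (discs placed by rejection sampling under a pairwise
overlap bound), so every pipeline stage can be scored against ground truth.

Default scale: 4 px/um, so the normal 6-8 um erythrocyte diameter renders
as a radius of 12-16 px on a 300x300 canvas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "StainPalette",
    "SmearParams",
    "GroundTruth",
    "PlacementError",
    "generate_smear",
    "circle_overlap_fraction",
    "rotate_hue",
]

PLT = "PLT"
_MAX_TRIALS = 10_000


@dataclass(frozen=True)
class StainPalette:
    """Mean RGB of each rendered structure (before jitter and noise)."""

    background: tuple[float, float, float] = (230.0, 225.0, 235.0)
    rbc_rim: tuple[float, float, float] = (200.0, 140.0, 140.0)
    #: basophilic (moderately dark) cytoplasm: the nucleus-cytoplasm edge
    #: must be a weaker gradient wall than the cell-background edge, or no
    #: gradient-watershed method can hand the cytoplasm to the nucleus seed
    cytoplasm: tuple[float, float, float] = (150.0, 140.0, 190.0)
    #: condensed chromatin stains deep blue-purple; it must dominate the
    #: saturation/intensity ratio for the ratio histogram to be bimodal
    nucleus: tuple[float, float, float] = (70.0, 45.0, 120.0)
    platelet: tuple[float, float, float] = (110.0, 70.0, 150.0)
    #: central pallor strength of the biconcave RBC profile, 0 = flat disc
    rbc_pallor: float = 0.45
    #: brightness factor of the ~1.5 px membrane ring drawn on every cell;
    #: overlapping cells must show their edges or no edge-based method can
    #: separate them
    membrane_shade: float = 0.7
    membrane_width: float = 1.5


@dataclass(frozen=True)
class SmearParams:
    width: int = 300
    height: int = 300
    n_rbc: int = 10
    n_wbc: int = 1
    n_platelet: int = 2
    rbc_radius_range: tuple[float, float] = (12.0, 16.0)
    wbc_radius_range: tuple[float, float] = (20.0, 26.0)
    platelet_radius_range: tuple[float, float] = (4.0, 6.0)
    max_overlap_fraction: float = 0.2
    stain: StainPalette = field(default_factory=StainPalette)
    #: sd of the per-image global shift of each palette channel
    stain_jitter_sd: float = 4.0
    noise_sd: float = 3.0
    blur_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for rng in (self.rbc_radius_range, self.wbc_radius_range, self.platelet_radius_range):
            if rng[0] <= 0 or rng[1] < rng[0]:
                raise ValueError(f"invalid radius range {rng}")
        if not 0 <= self.max_overlap_fraction < 1:
            raise ValueError("max_overlap_fraction must be in [0, 1)")


@dataclass(frozen=True)
class GroundTruth:
    instance_labels: np.ndarray  # 0 background, 1..N instances (paint order)
    classes: list[str]  # per instance: "WBC" | "RBC" | "PLT"
    centers: list[tuple[float, float]]  # (row, col)
    radii: list[float]
    nucleus_mask: np.ndarray

    @property
    def n_instances(self) -> int:
        return len(self.classes)

    def cell_ids(self) -> list[int]:
        """Instance ids (1-based) of cells, i.e. everything but platelets."""
        return [i + 1 for i, c in enumerate(self.classes) if c != PLT]


class PlacementError(RuntimeError):
    """Rejection sampling could not place all requested objects."""


def circle_overlap_fraction(c1, r1, c2, r2) -> float:
    """Intersection area of two discs divided by the smaller disc's area."""
    d = float(np.hypot(c1[0] - c2[0], c1[1] - c2[1]))
    if d >= r1 + r2:
        return 0.0
    rs, rl = min(r1, r2), max(r1, r2)
    if d <= rl - rs:
        inter = np.pi * rs * rs
    else:
        a1 = r1 * r1 * np.arccos((d * d + r1 * r1 - r2 * r2) / (2 * d * r1))
        a2 = r2 * r2 * np.arccos((d * d + r2 * r2 - r1 * r1) / (2 * d * r2))
        a3 = 0.5 * np.sqrt(
            (-d + r1 + r2) * (d + r1 - r2) * (d - r1 + r2) * (d + r1 + r2)
        )
        inter = a1 + a2 - a3
    return float(inter / (np.pi * rs * rs))


def _place(
    rng: np.random.Generator,
    n: int,
    radius_range: tuple[float, float],
    shape: tuple[int, int],
    existing: list[tuple[tuple[float, float], float]],
    max_overlap: float,
    what: str,
) -> list[tuple[tuple[float, float], float]]:
    placed: list[tuple[tuple[float, float], float]] = []
    H, W = shape
    for i in range(n):
        for _ in range(_MAX_TRIALS):
            r = float(rng.uniform(*radius_range))
            margin = r + 2.0
            if 2 * margin >= min(H, W):
                raise PlacementError(f"canvas too small for {what} radius {r:.1f}")
            cy = float(rng.uniform(margin, H - margin))
            cx = float(rng.uniform(margin, W - margin))
            ok = all(
                circle_overlap_fraction((cy, cx), r, c, rr) <= max_overlap
                for c, rr in existing + placed
            )
            if ok:
                placed.append(((cy, cx), r))
                break
        else:
            raise PlacementError(
                f"could only place {len(placed)} of {n} {what}s "
                f"(plus {len(existing)} existing) at overlap "
                f"<= {max_overlap} after {_MAX_TRIALS} trials"
            )
    return placed


def _disc_mask(shape, center, radius) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius * radius


def generate_smear(params: SmearParams) -> tuple[np.ndarray, GroundTruth]:
    """Render a synthetic smear; deterministic for a fixed seed.

    Instances are painted RBCs first, then WBCs (so nuclei are never
    occluded), then platelets on free background; ``instance_labels`` records
    the topmost instance per pixel while centres/radii keep the exact
    pre-noise geometry.
    """
    rng = np.random.default_rng(params.seed)
    H, W = params.height, params.width
    pal = params.stain

    def jitter(color):
        return np.clip(
            np.asarray(color, dtype=np.float64)
            + rng.normal(0.0, params.stain_jitter_sd, size=3),
            0,
            255,
        )

    bg = jitter(pal.background)
    col_rim = jitter(pal.rbc_rim)
    col_cyt = jitter(pal.cytoplasm)
    col_nuc = jitter(pal.nucleus)
    col_plt = jitter(pal.platelet)

    # placement: WBCs first (largest, hardest to fit), then RBCs; platelets
    # go on free background only
    wbcs = _place(rng, params.n_wbc, params.wbc_radius_range, (H, W), [], params.max_overlap_fraction, "WBC")
    rbcs = _place(rng, params.n_rbc, params.rbc_radius_range, (H, W), wbcs, params.max_overlap_fraction, "RBC")
    plts = _place(rng, params.n_platelet, params.platelet_radius_range, (H, W), wbcs + rbcs, 0.0, "platelet")

    img = np.empty((H, W, 3), dtype=np.float64)
    img[:] = bg
    labels = np.zeros((H, W), dtype=np.int64)
    nucleus_mask = np.zeros((H, W), dtype=bool)
    classes: list[str] = []
    centers: list[tuple[float, float]] = []
    radii: list[float] = []

    yy, xx = np.mgrid[:H, :W]

    inst = 0
    for (cy, cx), r in rbcs:
        inst += 1
        rho2 = ((yy - cy) ** 2 + (xx - cx) ** 2) / (r * r)
        disc = rho2 <= 1.0
        # biconcave profile: parabolic pallor cap over the central 60%
        g = np.clip(1.0 - rho2 / 0.36, 0.0, 1.0)
        pallor = pal.rbc_pallor * g[disc]
        img[disc] = col_rim + pallor[:, None] * (bg - col_rim)
        labels[disc] = inst
        classes.append("RBC")
        centers.append((cy, cx))
        radii.append(r)
    for (cy, cx), r in wbcs:
        inst += 1
        disc = _disc_mask((H, W), (cy, cx), r)
        img[disc] = col_cyt
        labels[disc] = inst
        # lobed nucleus: union of 2-4 overlapping lobes around the centre;
        # cells this size (10-13 um) are lymphocyte-like, with a high
        # nuclear:cytoplasmic ratio
        n_lobes = int(rng.integers(2, 5))
        angles = rng.uniform(0, 2 * np.pi, n_lobes)
        nuc = np.zeros((H, W), dtype=bool)
        for a in angles:
            ly = cy + 0.20 * r * np.sin(a)
            lx = cx + 0.20 * r * np.cos(a)
            nuc |= _disc_mask((H, W), (ly, lx), 0.60 * r)
        nuc &= disc
        # feathered chromatin edge: the nucleus-cytoplasm transition is
        # diffraction-softened in brightfield, unlike the crisp membrane
        alpha = np.clip(ndimage.gaussian_filter(nuc.astype(np.float64), 1.8) * 1.15, 0, 1)
        alpha[~disc] = 0.0
        img = img * (1 - alpha[..., None]) + col_nuc * alpha[..., None]
        nucleus_mask |= nuc
        classes.append("WBC")
        centers.append((cy, cx))
        radii.append(r)
    # membrane pass: every cell's edge ring is drawn on top, so the shared
    # boundary of overlapping cells stays visible (as it does on a smear)
    for (cy, cx), r in rbcs + wbcs:
        ring = _disc_mask((H, W), (cy, cx), r) & ~_disc_mask(
            (H, W), (cy, cx), max(r - pal.membrane_width, 1.0)
        )
        body = col_cyt if ((cy, cx), r) in wbcs else col_rim
        # darker and slightly desaturated: membranes absorb, they don't stain
        grey = np.full(3, body.mean())
        img[ring] = pal.membrane_shade * (0.75 * body + 0.25 * grey)
    for (cy, cx), r in plts:
        inst += 1
        disc = _disc_mask((H, W), (cy, cx), r)
        img[disc] = col_plt
        labels[disc] = inst
        classes.append(PLT)
        centers.append((cy, cx))
        radii.append(r)

    if params.blur_sigma > 0:
        for c in range(3):
            img[..., c] = ndimage.gaussian_filter(img[..., c], params.blur_sigma)
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, size=img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return img, GroundTruth(
        instance_labels=labels,
        classes=classes,
        centers=centers,
        radii=radii,
        nucleus_mask=nucleus_mask,
    )


def rotate_hue(img: np.ndarray, degrees: float) -> np.ndarray:
    """Rotate every pixel's hue by `degrees` (HSV), preserving S and V.

    Used to emulate a different staining scheme while keeping saturation
    and brightness structure intact.
    """
    a = np.asarray(img, dtype=np.float64) / 255.0
    r, g, b = a[..., 0], a[..., 1], a[..., 2]
    mx = a.max(axis=2)
    mn = a.min(axis=2)
    diff = mx - mn
    h = np.zeros_like(mx)
    nz = diff > 0
    rmax = nz & (mx == r)
    gmax = nz & (mx == g) & ~rmax
    bmax = nz & (mx == b) & ~rmax & ~gmax
    h[rmax] = ((g - b)[rmax] / diff[rmax]) % 6
    h[gmax] = (b - r)[gmax] / diff[gmax] + 2
    h[bmax] = (r - g)[bmax] / diff[bmax] + 4
    h = (h * 60.0 + degrees) % 360.0
    s = np.where(mx > 0, diff / np.where(mx > 0, mx, 1.0), 0.0)
    v = mx
    c = v * s
    hp = h / 60.0
    x = c * (1 - np.abs(hp % 2 - 1))
    z = np.zeros_like(c)
    conds = [
        (hp < 1, (c, x, z)),
        ((hp >= 1) & (hp < 2), (x, c, z)),
        ((hp >= 2) & (hp < 3), (z, c, x)),
        ((hp >= 3) & (hp < 4), (z, x, c)),
        ((hp >= 4) & (hp < 5), (x, z, c)),
        (hp >= 5, (c, z, x)),
    ]
    out = np.zeros_like(a)
    for cond, (rr, gg, bb) in conds:
        out[..., 0][cond] = rr[cond]
        out[..., 1][cond] = gg[cond]
        out[..., 2][cond] = bb[cond]
    out += (v - c)[..., None]
    return np.clip(np.round(out * 255.0), 0, 255).astype(np.uint8)
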