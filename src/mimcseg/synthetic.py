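"""Ground-truthed synthetic multichannel tissue images.

Emulates the structure of an IMC acquisition of a densely packed mouse lung
tumour: spatially coherent tissue domains (a tumour blob with an interface
band, structural vessels, normal tissue elsewhere), several cell phenotypes
with distinct nucleus sizes placed by a hard-core point process, a spindle
cell type (fibroblast-like, alpha-SMA analogue) drawn as bent ribbons with no
detectable nucleus, per-type marker signatures with Poisson count noise,
adjacency spillover (boundary-pixel mixing between touching cells — the
spatial "signal bleed" failure mode segmentation strategies are judged on),
isolated hot pixels, and a spatially flat ambient reference channel (Xe134
analogue).

Everything is deterministic given the config seed, and every stage of the
pipeline can be tested against the returned ground truth with no download.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .io_formats import AnnotationSet, ImageStack, PanelEntry
from .segmentation import DOMAIN_CODES

__all__ = [
    "CellTypeSpec",
    "TissueConfig",
    "GroundTruth",
    "generate_tissue",
    "generate_annotations",
    "scribbles_from_truth",
    "recovery",
    "default_config",
]

#: marker channels of the synthetic panel, in panel order
PANEL_TAGS = [
    ("Ir191", "DNA1"),
    ("Ir193", "DNA2"),
    ("Xe134", "Xe134"),
    ("CD3", "CD3"),
    ("F480", "F480"),
    ("aSMA", "aSMA"),
    ("CD44", "CD44"),
    ("PECAM", "PECAM"),
    ("EPCAM", "EPCAM"),
]
MARKER_CHANNELS = ["CD3", "F480", "aSMA", "CD44", "PECAM", "EPCAM"]


@dataclass(frozen=True)
class CellTypeSpec:
    """Geometry, abundance and marker signature of one synthetic cell type."""

    name: str
    count: int
    cell_diameter: float
    nucleus_diameter_mean: float
    nucleus_diameter_sd: float
    signature: dict  # marker channel -> expected counts on the cell support
    domains: tuple[str, ...]  # allowed placement domains
    spindle: bool = False  # drawn as a bent ribbon, no nucleus


@dataclass
class TissueConfig:
    """Study conditions for one synthetic ROI."""

    size: int = 512
    tumour_radius: float = 170.0
    tumour_waviness: float = 18.0
    n_vessels: int = 3
    vessel_width: float = 7.0
    interface_width: float = 6.0
    cell_types: tuple[CellTypeSpec, ...] = ()
    spillover: float = 0.15
    poisson_noise: bool = True
    hot_pixel_rate: float = 3e-4
    hot_pixel_amplitude: float = 500.0
    dna_intensity: tuple[float, float] = (15.0, 12.0)  # Ir191, Ir193 on nuclei
    ambient_xe: float = 5.0
    # nonspecific background counts on every antibody channel, part of the
    # Poisson noise model (real acquisitions never have exactly-zero
    # channels; without this, top-k enrichment denominators degenerate)
    ambient_background: float = 0.3
    seed: int = 0
    roi_id: str = "synthetic_roi"
    treatment: str = "vehicle"

    def __post_init__(self):
        if not (0 <= self.spillover < 1):
            raise ValueError("spillover must lie in [0, 1)")
        if self.hot_pixel_rate < 0:
            raise ValueError("hot_pixel_rate must be >= 0")
        if not self.cell_types:
            self.cell_types = _default_cell_types()
        elif isinstance(self.cell_types[0], dict):
            # YAML configs carry cell types as plain mappings
            self.cell_types = tuple(
                CellTypeSpec(**{**d, "domains": tuple(d["domains"]),
                                "signature": dict(d["signature"])})
                for d in self.cell_types
            )
        else:
            self.cell_types = tuple(self.cell_types)
        self.dna_intensity = tuple(self.dna_intensity)


def _default_cell_types() -> tuple[CellTypeSpec, ...]:
    """Defaults sized for a 512x512 ROI with ~600 cells.

    Lymphocytes are small-nucleated, fibroblasts are spindle cells expressing
    only the aSMA analogue, tumour cells are large and fill the tumour blob.
    """
    return (
        CellTypeSpec("lymphocyte", 90, 7.0, 5.0, 0.5,
                     {"CD3": 20.0}, ("normal", "interface")),
        CellTypeSpec("macrophage", 90, 12.0, 7.0, 0.8,
                     {"F480": 20.0}, ("tumour", "interface")),
        CellTypeSpec("fibroblast", 40, 0.0, 0.0, 0.0,
                     {"aSMA": 20.0}, ("tumour", "structural"), spindle=True),
        CellTypeSpec("normal", 150, 12.0, 8.0, 0.8,
                     {"PECAM": 18.0, "EPCAM": 4.0}, ("normal",)),
        CellTypeSpec("tumour", 220, 14.0, 10.0, 1.0,
                     {"CD44": 18.0}, ("tumour",)),
    )


def default_config(seed: int = 0, **overrides) -> TissueConfig:
    return replace(TissueConfig(seed=seed), **overrides)


@dataclass
class GroundTruth:
    """Everything the generator knows about the planted tissue."""

    stack: ImageStack
    nuclei: np.ndarray
    cells: np.ndarray
    domains: np.ndarray
    cell_table: pd.DataFrame
    config: TissueConfig


def _domain_layout(cfg: TissueConfig, rng: np.random.Generator):
    """Smooth tumour blob + vessels + interface band on an otherwise
    normal-tissue canvas.  Returns the coded domain mask."""
    n = cfg.size
    yy, xx = np.indices((n, n), dtype=float)
    cy = cx = n / 2.0
    theta = np.arctan2(yy - cy, xx - cx)
    # wavy radius: few low-order harmonics for a smooth organic boundary
    r = np.hypot(yy - cy, xx - cx)
    wave = np.zeros_like(theta)
    for h in (2, 3, 5):
        wave += rng.normal(0, 1) * np.cos(h * theta + rng.uniform(0, 2 * np.pi))
    boundary = cfg.tumour_radius + cfg.tumour_waviness * wave / 3.0
    tumour = r <= boundary

    domains = np.full((n, n), DOMAIN_CODES["normal"], dtype=np.uint8)
    domains[tumour] = DOMAIN_CODES["tumour"]

    # structural vessels: wavy near-vertical ribbons
    for _ in range(cfg.n_vessels):
        x0 = rng.uniform(0.1, 0.9) * n
        amp = rng.uniform(5, 20)
        freq = rng.uniform(1.0, 2.5) * 2 * np.pi / n
        phase = rng.uniform(0, 2 * np.pi)
        centre = x0 + amp * np.sin(freq * yy + phase)
        vessel = np.abs(xx - centre) <= cfg.vessel_width / 2.0
        domains[vessel] = DOMAIN_CODES["structural"]

    # interface: band straddling the tumour boundary
    if cfg.interface_width > 0:
        inside = ndi.distance_transform_edt(tumour)
        outside = ndi.distance_transform_edt(~tumour)
        band = (inside <= cfg.interface_width / 2) & tumour
        band |= (outside <= cfg.interface_width / 2) & ~tumour
        domains[band & (domains != DOMAIN_CODES["structural"])] = DOMAIN_CODES["interface"]
    return domains


def _hardcore_sample(
    allowed: np.ndarray,
    count: int,
    radius: float,
    existing: list[tuple[float, float, float]],
    rng: np.random.Generator,
    max_attempts_factor: int = 200,
):
    """Sample ``count`` centres uniformly on ``allowed`` pixels, keeping
    centre distance >= own radius + other's radius (hard core).  Raises when
    the density is too high for the constraint."""
    coords = np.argwhere(allowed)
    if coords.size == 0 and count > 0:
        raise ValueError("no allowed pixels for placement")
    accepted = []
    attempts = 0
    budget = max_attempts_factor * max(count, 1)
    pts = np.array([(y, x) for y, x, _ in existing], dtype=float).reshape(-1, 2)
    rads = np.array([r for _, _, r in existing], dtype=float)
    while len(accepted) < count:
        if attempts >= budget:
            raise ValueError(
                f"could not place {count} cells after {budget} attempts; "
                "density too high for the hard-core constraint"
            )
        attempts += 1
        y, x = coords[rng.integers(len(coords))]
        y = y + rng.uniform(-0.5, 0.5)
        x = x + rng.uniform(-0.5, 0.5)
        if len(pts):
            d = np.hypot(pts[:, 0] - y, pts[:, 1] - x)
            if np.any(d < rads + radius):
                continue
        accepted.append((y, x))
        pts = np.vstack([pts, [y, x]])
        rads = np.append(rads, radius)
    return accepted


def _ribbon(center, length, width, rng, shape):
    """Rasterise a bent elongated ribbon (quadratic Bezier spine, dilated)."""
    cy, cx = center
    theta = rng.uniform(0, np.pi)
    dy, dx = np.sin(theta), np.cos(theta)
    p0 = np.array([cy - dy * length / 2, cx - dx * length / 2])
    p2 = np.array([cy + dy * length / 2, cx + dx * length / 2])
    bend = rng.uniform(0.15, 0.35) * length * rng.choice([-1.0, 1.0])
    p1 = np.array([cy - dx * bend, cx + dy * bend])  # perpendicular offset
    t = np.linspace(0, 1, int(3 * length))[:, None]
    spine = (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t**2 * p2
    mask = np.zeros(shape, dtype=bool)
    iy = np.clip(np.round(spine[:, 0]).astype(int), 0, shape[0] - 1)
    ix = np.clip(np.round(spine[:, 1]).astype(int), 0, shape[1] - 1)
    mask[iy, ix] = True
    half = max(1, int(round(width / 2)))
    return ndi.binary_dilation(mask, iterations=half)


def generate_tissue(config: TissueConfig | None = None) -> GroundTruth:
    """Generate one ground-truthed synthetic ROI.

    Cells are painted as disks clipped to the Voronoi region of their centre
    (so touching cells share a straight boundary rather than overlapping),
    nuclei as concentric smaller disks; spindle cells as bent ribbons without
    nuclei.  Channel intensities are the per-type signature on the cell
    support, plus boundary spillover from adjacent cells, plus Poisson noise
    and hot pixels when enabled.
    """
    cfg = config or TissueConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.size
    domains = _domain_layout(cfg, rng)

    # ---- place cells --------------------------------------------------
    placed: list[dict] = []
    existing: list[tuple[float, float, float]] = []
    for spec in cfg.cell_types:
        if spec.count == 0:
            continue
        allowed = np.isin(domains, [DOMAIN_CODES[d] for d in spec.domains])
        # ribbons need room along their spine; use half-length as the core
        radius = (22.0 / 2 * 0.45) if spec.spindle else spec.cell_diameter / 2 * 0.9
        centres = _hardcore_sample(allowed, spec.count, radius, existing, rng)
        for cy, cx in centres:
            nuc_d = (
                0.0
                if spec.spindle
                else max(2.0, rng.normal(spec.nucleus_diameter_mean, spec.nucleus_diameter_sd))
            )
            placed.append(
                {"type": spec, "cy": cy, "cx": cx, "nuc_d": nuc_d}
            )
            existing.append((cy, cx, radius))

    cells = np.zeros((n, n), dtype=np.int32)
    nuclei = np.zeros((n, n), dtype=np.int32)

    disk_cells = [c for c in placed if not c["type"].spindle]
    if disk_cells:
        centres = np.array([(c["cy"], c["cx"]) for c in disk_cells])
        tree = cKDTree(centres)
        yy, xx = np.indices((n, n), dtype=float)
        pix = np.column_stack([yy.ravel(), xx.ravel()])
        dist, owner = tree.query(pix, k=1)
        radii = np.array([c["type"].cell_diameter / 2 for c in disk_cells])
        inside = dist <= radii[owner]
        cells.ravel()[inside] = owner[inside] + 1

    label = len(disk_cells)
    for c in placed:
        if not c["type"].spindle:
            continue
        label += 1
        ribbon = _ribbon((c["cy"], c["cx"]), length=22.0, width=3.0, rng=rng, shape=(n, n))
        ribbon &= cells == 0
        cells[ribbon] = label
        c["label"] = label
    for i, c in enumerate(disk_cells):
        c["label"] = i + 1

    # nuclei: concentric disks clipped to the cell support
    yy, xx = np.indices((n, n), dtype=float)
    for c in disk_cells:
        r = c["nuc_d"] / 2
        y0, y1 = int(max(0, c["cy"] - r - 2)), int(min(n, c["cy"] + r + 3))
        x0, x1 = int(max(0, c["cx"] - r - 2)), int(min(n, c["cx"] + r + 3))
        local = (yy[y0:y1, x0:x1] - c["cy"]) ** 2 + (xx[y0:y1, x0:x1] - c["cx"]) ** 2 <= r * r
        local &= cells[y0:y1, x0:x1] == c["label"]
        nuclei[y0:y1, x0:x1][local] = c["label"]

    # drop cells whose support vanished entirely (crowded ribbons)
    kept = np.unique(cells)
    kept = kept[kept > 0]
    placed = [c for c in placed if c.get("label") in set(kept.tolist())]

    # ---- paint expected intensities -----------------------------------
    tags = [PanelEntry(metal_tag=t, marker=m) for t, m in PANEL_TAGS]
    expected = np.zeros((len(tags), n, n), dtype=np.float64)
    marker_index = {m: i for i, (_, m) in enumerate(PANEL_TAGS)}

    for c in placed:
        sup = cells == c["label"]
        for marker, value in c["type"].signature.items():
            expected[marker_index[marker]][sup] += value
    nuc_sup = nuclei > 0
    expected[marker_index["DNA1"]][nuc_sup] += cfg.dna_intensity[0]
    expected[marker_index["DNA2"]][nuc_sup] += cfg.dna_intensity[1]
    expected[marker_index["Xe134"]] += cfg.ambient_xe

    # ---- adjacency spillover: boundary-pixel mixing -------------------
    if cfg.spillover > 0:
        shifts = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
        foreign_sum = np.zeros_like(expected)
        foreign_cnt = np.zeros((n, n), dtype=np.float64)
        for dy, dx in shifts:
            lab_sh = np.roll(np.roll(cells, dy, axis=0), dx, axis=1)
            ex_sh = np.roll(np.roll(expected, dy, axis=1), dx, axis=2)
            foreign = (lab_sh > 0) & (cells > 0) & (lab_sh != cells)
            foreign_cnt += foreign
            foreign_sum[:, foreign] += ex_sh[:, foreign]
        mix = foreign_cnt > 0
        f = cfg.spillover
        for ch in range(len(tags)):
            if PANEL_TAGS[ch][1] == "Xe134":
                continue
            mixed = foreign_sum[ch, mix] / foreign_cnt[mix]
            expected[ch, mix] = (1 - f) * expected[ch, mix] + f * mixed

    # ---- noise and artefacts ------------------------------------------
    if cfg.poisson_noise:
        # nonspecific antibody background enters through the noise model on
        # every channel except the ambient reference
        noisy_expect = expected.copy()
        if cfg.ambient_background > 0:
            for ch, (_, marker) in enumerate(PANEL_TAGS):
                if marker != "Xe134":
                    noisy_expect[ch] += cfg.ambient_background
        pixels = rng.poisson(noisy_expect).astype(np.float64)
    else:
        pixels = expected.copy()
    if cfg.hot_pixel_rate > 0:
        n_hot = rng.poisson(cfg.hot_pixel_rate * n * n)
        for _ in range(n_hot):
            ch = rng.integers(len(tags))
            y, x = rng.integers(n), rng.integers(n)
            pixels[ch, y, x] += cfg.hot_pixel_amplitude

    stack = ImageStack(tags, pixels, roi_id=cfg.roi_id)

    # ---- ground-truth cell table --------------------------------------
    rows = []
    for c in placed:
        sup = cells == c["label"]
        ys, xs = np.nonzero(sup)
        rows.append(
            {
                "cell_id": c["label"],
                "centroid_x": xs.mean(),
                "centroid_y": ys.mean(),
                "area": int(sup.sum()),
                "cell_type": c["type"].name,
                "roi_id": cfg.roi_id,
                "treatment": cfg.treatment,
            }
        )
    columns = [
        "cell_id", "centroid_x", "centroid_y", "area",
        "cell_type", "roi_id", "treatment",
    ]
    table = (
        pd.DataFrame(rows).sort_values("cell_id").reset_index(drop=True)
        if rows
        else pd.DataFrame(columns=columns)
    )
    return GroundTruth(stack, nuclei, cells, domains, table, cfg)


def generate_annotations(
    ground_truth: GroundTruth,
    n_per_type: int | dict,
    jitter_sd: float = 0.0,
    seed: int = 0,
) -> AnnotationSet:
    """Emulate a manually annotated validation set.

    Samples ``n_per_type`` true cells per type and records their centroid
    plus isotropic Gaussian jitter.  Requesting more cells than exist is an
    error.  Labels are the *marker* of the type (the annotation workflow
    records "CD4+ cells", not cluster names), taken as the dominant
    signature channel.
    """
    rng = np.random.default_rng(seed)
    xs, ys, labels = [], [], []
    table = ground_truth.cell_table
    for spec in ground_truth.config.cell_types:
        want = (
            n_per_type.get(spec.name, 0)
            if isinstance(n_per_type, dict)
            else n_per_type
        )
        sub = table[table["cell_type"] == spec.name]
        if want > len(sub):
            raise ValueError(
                f"requested {want} annotations for {spec.name!r} but only "
                f"{len(sub)} cells exist"
            )
        if want == 0:
            continue
        pick = sub.sample(n=want, random_state=int(rng.integers(2**31)))
        marker = max(spec.signature, key=spec.signature.get)
        xs.extend(pick["centroid_x"] + rng.normal(0, jitter_sd, want))
        ys.extend(pick["centroid_y"] + rng.normal(0, jitter_sd, want))
        labels.extend([marker] * want)
    return AnnotationSet(np.array(xs), np.array(ys), np.array(labels, dtype=object))


def scribbles_from_truth(
    ground_truth: GroundTruth,
    class_names: list[str],
    n_per_class: int = 400,
    seed: int = 0,
    kind: str = "cells",
) -> np.ndarray:
    """Sparse training scribbles sampled from the ground truth.

    ``kind="cells"`` labels pixels by cell type (plus ``background``);
    ``kind="domains"`` labels pixels by tissue domain.  Returns an integer
    image with 0 = unlabelled and value ``k`` = ``class_names[k-1]``.
    """
    rng = np.random.default_rng(seed)
    gt = ground_truth
    out = np.zeros(gt.cells.shape, dtype=np.int32)
    if kind == "cells":
        type_img = np.zeros(gt.cells.shape, dtype=object)
        type_img[...] = "background"
        table = gt.cell_table.set_index("cell_id")
        lut = np.zeros(int(gt.cells.max()) + 1, dtype=object)
        lut[0] = "background"
        for cid, row in table.iterrows():
            lut[int(cid)] = row["cell_type"]
        type_img = lut[gt.cells]
    elif kind == "domains":
        from .segmentation import DOMAIN_NAMES

        names = np.array(DOMAIN_NAMES, dtype=object)
        type_img = names[gt.domains]
    else:
        raise ValueError(f"unknown scribble kind {kind!r}")

    for k, cls in enumerate(class_names, start=1):
        coords = np.argwhere(type_img == cls)
        if coords.size == 0:
            continue
        take = min(n_per_class, len(coords))
        pick = coords[rng.choice(len(coords), size=take, replace=False)]
        out[tuple(pick.T)] = k
    return out


def recovery(
    truth_table: pd.DataFrame,
    detected_table: pd.DataFrame,
    radius: float = 5.0,
) -> pd.Series:
    """Fraction of planted cells recovered, overall and per type.

    A planted cell is recovered when a detected cell centroid lies within
    ``radius`` of its true centroid; matching is one-to-one, greedy
    nearest-pair-first.  Returns a Series indexed by cell type plus
    ``"overall"`` and ``"non_spindle"`` rows.
    """
    tx = truth_table["centroid_x"].to_numpy(dtype=float)
    ty = truth_table["centroid_y"].to_numpy(dtype=float)
    dx = detected_table["centroid_x"].to_numpy(dtype=float)
    dy = detected_table["centroid_y"].to_numpy(dtype=float)
    d = np.hypot(tx[:, None] - dx[None, :], ty[:, None] - dy[None, :])
    cand = np.argwhere(d <= radius)
    matched = np.zeros(len(truth_table), dtype=bool)
    if cand.size:
        order = np.lexsort((cand[:, 1], cand[:, 0], d[cand[:, 0], cand[:, 1]]))
        used_det = np.zeros(len(detected_table), dtype=bool)
        for i in order:
            a, b = cand[i]
            if matched[a] or used_det[b]:
                continue
            matched[a] = True
            used_det[b] = True
    types = truth_table["cell_type"].to_numpy()
    out = {}
    for t in pd.unique(types):
        sel = types == t
        out[t] = matched[sel].mean()
    spindle_types = {"fibroblast"}
    non_spindle = ~np.isin(types, list(spindle_types))
    out["non_spindle"] = matched[non_spindle].mean() if non_spindle.any() else np.nan
    out["overall"] = matched.mean()
    return pd.Series(out)
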