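"""Synthetic lumbar-spine phantom generator.

Renders stylized frontal/lateral lumbar radiograph phantoms: five vertebral
bodies (L1-L5) stacked as bright rectangles separated by darker disc spaces,
optional pedicle-screw/rod instrumentation drawn as high-intensity hardware,
fused levels bridged by bony struts, and disc degeneration rendered as a
narrowed disc space.  Each phantom carries a templated report naming its
findings, a pixel mask over {background, vertebra, disc, instrumentation},
image-level binary labels, and word-to-pixel ground truth for every finding
word — the structure a global-local image-text alignment model consumes,
without any real patient data.

Coordinates are row-major, 0-based, origin top-left, (row, col) order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "PhantomSpec", "PhantomSample", "SplitManifest",
    "make_phantom", "render_report", "generate_dataset", "patient_split",
    "write_dataset", "load_manifest",
    "BACKGROUND", "VERTEBRA", "DISC", "INSTRUMENTATION",
    "DEGENERATION_THRESHOLD",
]

BACKGROUND, VERTEBRA, DISC, INSTRUMENTATION = 0, 1, 2, 3

#: disc_gap_fraction below this value renders (and labels) disc degeneration
DEGENERATION_THRESHOLD = 0.6


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and pathology of one phantom image.

    disc_gap_fraction has one entry per disc space (n_vertebrae - 1 entries);
    1.0 is normal spacing, values below :data:`DEGENERATION_THRESHOLD` flag
    degeneration.  instrumented_levels indexes vertebrae 0..n-1 (0 = L1);
    fused_levels holds (upper, lower) pairs of adjacent vertebra indices.
    """

    image_height: int = 64
    image_width: int = 64
    n_vertebrae: int = 5
    disc_gap_fraction: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0)
    instrumented_levels: frozenset[int] = frozenset()
    fused_levels: frozenset[tuple[int, int]] = frozenset()
    noise_sd: float = 0.02
    jitter: float = 0.5
    seed: int = 0
    view: str = "AP"

    def __post_init__(self):
        if self.image_height < 16 or self.image_width < 16:
            raise ValueError("image dimensions must be at least 16 pixels")
        if self.n_vertebrae < 1:
            raise ValueError("n_vertebrae must be >= 1")
        if len(self.disc_gap_fraction) != max(self.n_vertebrae - 1, 0):
            raise ValueError(
                f"disc_gap_fraction needs {self.n_vertebrae - 1} entries, "
                f"got {len(self.disc_gap_fraction)}")
        if any(f <= 0 for f in self.disc_gap_fraction):
            raise ValueError("disc_gap_fraction entries must be positive")
        if any(not (0 <= i < self.n_vertebrae) for i in self.instrumented_levels):
            raise ValueError("instrumented level index out of range")
        for a, b in self.fused_levels:
            if not (0 <= a < self.n_vertebrae and 0 <= b < self.n_vertebrae):
                raise ValueError("fused level index out of range")
            if abs(a - b) != 1:
                raise ValueError("fused_levels must be adjacent pairs")
        if self.noise_sd < 0 or self.jitter < 0:
            raise ValueError("noise_sd and jitter must be >= 0")
        if self.view not in ("AP", "lateral"):
            raise ValueError("view must be 'AP' or 'lateral'")

    @property
    def labels(self) -> dict[str, int]:
        """Image-level binary labels implied by the spec."""
        return {
            "degeneration": int(any(f < DEGENERATION_THRESHOLD
                                    for f in self.disc_gap_fraction)),
            "fusion": int(bool(self.fused_levels)),
            "instrumentation": int(bool(self.instrumented_levels)),
        }


@dataclass
class PhantomSample:
    image: np.ndarray                       # H x W float in [0, 1]
    mask: np.ndarray                        # H x W int in {0,1,2,3}
    report: str
    concept_regions: dict[str, set[tuple[int, int]]]
    labels: dict[str, int]
    patient_id: str
    view: str
    spec: PhantomSpec | None = None


@dataclass
class SplitManifest:
    train: list[str]
    val: list[str]
    test: list[str]
    ratios: tuple[float, float, float]

    def to_json(self) -> str:
        return json.dumps({"train": self.train, "val": self.val,
                           "test": self.test, "ratios": list(self.ratios)})

    @classmethod
    def from_json(cls, text: str) -> "SplitManifest":
        d = json.loads(text)
        return cls(d["train"], d["val"], d["test"], tuple(d["ratios"]))


# ---------------------------------------------------------------------------
# rendering

def _layout(spec: PhantomSpec, rng: np.random.Generator):
    """Compute vertebra and disc row spans plus the column span of the spine.

    Returns (vert_rows, gap_rows, col_spans) where vert_rows[i] = (r0, r1)
    half-open row span of vertebra i, gap_rows[g] = (r0, r1) of disc space g,
    and col_spans[i] = (c0, c1) per-vertebra column span (jittered).
    """
    H, W = spec.image_height, spec.image_width
    n = spec.n_vertebrae
    margin = max(2, H // 16)
    avail = H - 2 * margin
    # nominal: vertebra height h, full disc gap 0.5*h scaled per level
    gap_scale = np.asarray(spec.disc_gap_fraction) if n > 1 else np.zeros(0)
    h = avail / (n + 0.5 * gap_scale.sum()) if n else avail
    vert_rows, gap_rows = [], []
    r = float(margin)
    for i in range(n):
        r0 = int(round(r))
        r1 = int(round(r + h))
        vert_rows.append((r0, max(r1, r0 + 1)))
        r += h
        if i < n - 1:
            g = 0.5 * h * gap_scale[i]
            gap_rows.append((int(round(r)), max(int(round(r + g)), int(round(r)) + 1)))
            r += g

    width = int(W * (0.34 if spec.view == "AP" else 0.26))
    center = W // 2 + (0 if spec.view == "AP" else -W // 10)
    col_spans = []
    for i in range(n):
        dx = rng.normal(0.0, spec.jitter)
        dw = rng.normal(0.0, spec.jitter)
        w_i = max(4, int(round(width + dw)))
        c0 = int(round(center - w_i / 2 + dx))
        c0 = min(max(c0, 1), W - w_i - 1)
        col_spans.append((c0, c0 + w_i))
    return vert_rows, gap_rows, col_spans


def _hardware_pixels(spec: PhantomSpec, geometry):
    """Pixel support of screws (per level) and the rod, from geometry alone."""
    vert_rows, _, col_spans = geometry
    W = spec.image_width
    screws: dict[int, set[tuple[int, int]]] = {}
    instr = sorted(spec.instrumented_levels)
    for i in instr:
        r0, r1 = vert_rows[i]
        c0, c1 = col_spans[i]
        rm = (r0 + r1) // 2
        bar_h = max(2, (r1 - r0) // 3)
        bar_w = max(3, (c1 - c0) // 3)
        pixels: set[tuple[int, int]] = set()
        for cs, ce in (((c0 - bar_w), c0 + 1), ((c1 - 1), c1 + bar_w)):
            cs, ce = max(cs, 0), min(ce, W)
            rr0, rr1 = rm - bar_h // 2, rm - bar_h // 2 + bar_h
            pixels.update((r, c) for r in range(rr0, rr1) for c in range(cs, ce))
        screws[i] = pixels
    rod: set[tuple[int, int]] = set()
    if instr:
        rod_c = max(min(col_spans[i][1] + 1 for i in instr), 0)
        rod_w = 2
        r_top = vert_rows[min(instr)][0]
        r_bot = vert_rows[max(instr)][1]
        rc0, rc1 = min(rod_c, W - rod_w), min(rod_c + rod_w, W)
        rod = {(r, c) for r in range(r_top, r_bot) for c in range(rc0, rc1)}
    return screws, rod


def render_report(spec: PhantomSpec, rng: np.random.Generator,
                  geometry=None) -> tuple[str, dict[str, set[tuple[int, int]]]]:
    """Assemble a templated lowercase report plus word-to-pixel ground truth.

    Finding words ("degeneration", "screw", "fixation", "rod",
    "instrumentation", "fusion") each map to the pixel support of the levels
    they describe.  A disc space is named by its upper vertebra only (the
    "l2 disc space" lies below L2), so reports that differ in one
    degeneration level differ in exactly one token.
    """
    if geometry is None:
        geometry = _layout(spec, np.random.default_rng(spec.seed))
    vert_rows, gap_rows, col_spans = geometry

    sentences = [f"lumbar spine radiograph {spec.view.lower()} view ."]
    sentences.append(f"{_COUNT_WORDS.get(spec.n_vertebrae, str(spec.n_vertebrae))} "
                     "lumbar vertebral bodies are visualized .")
    regions: dict[str, set[tuple[int, int]]] = {}

    def gap_pixels(g: int) -> set[tuple[int, int]]:
        r0, r1 = gap_rows[g]
        c0a, c1a = col_spans[g]
        c0b, c1b = col_spans[g + 1]
        c0, c1 = min(c0a, c0b), max(c1a, c1b)
        return {(r, c) for r in range(r0, r1) for c in range(c0, c1)}

    degen = [g for g, f in enumerate(spec.disc_gap_fraction)
             if f < DEGENERATION_THRESHOLD]
    for g in degen:
        sentences.append(f"disc space narrowing with degeneration at the "
                         f"l{g + 1} disc space .")
        regions.setdefault("degeneration", set()).update(gap_pixels(g))

    fused = sorted(spec.fused_levels)
    for a, b in fused:
        g = min(a, b)
        sentences.append(f"interbody fusion bridging the l{g + 1} disc space .")
        regions.setdefault("fusion", set()).update(gap_pixels(g))

    instr = sorted(spec.instrumented_levels)
    for i in instr:
        sentences.append(f"pedicle screw fixation with rod instrumentation "
                         f"at the l{i + 1} vertebra .")
    if instr:
        screws, rod = _hardware_pixels(spec, geometry)
        screw_pixels = set().union(*screws.values())
        regions["screw"] = set(screw_pixels)
        regions["rod"] = set(rod)
        regions["fixation"] = screw_pixels | rod
        regions["instrumentation"] = screw_pixels | rod

    if not (degen or fused or instr):
        sentences.append("vertebral bodies show normal alignment .")
        sentences.append("no instrumentation or degeneration is seen .")

    return " ".join(sentences), regions


_COUNT_WORDS = {1: "one", 2: "two", 3: "three", 4: "four", 5: "five", 6: "six"}


def make_phantom(spec: PhantomSpec) -> PhantomSample:
    """Render one phantom image with mask, report, labels and ground truth.

    Deterministic: identical specs (including seed) yield bit-identical
    samples.
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.image_height, spec.image_width
    geometry = _layout(spec, rng)
    vert_rows, gap_rows, col_spans = geometry

    image = np.full((H, W), 0.08)
    mask = np.zeros((H, W), dtype=np.int64)

    # soft tissue column behind the spine
    c_lo = min(c for c, _ in col_spans) - 3
    c_hi = max(c for _, c in col_spans) + 3
    image[:, max(c_lo, 0):min(c_hi, W)] += 0.07

    # vertebral bodies
    for (r0, r1), (c0, c1) in zip(vert_rows, col_spans):
        image[r0:r1, c0:c1] = 0.70
        image[r0:r1, c0:c0 + 1] = 0.80          # cortical edges
        image[r0:r1, c1 - 1:c1] = 0.80
        mask[r0:r1, c0:c1] = VERTEBRA

    # disc spaces
    for g, (r0, r1) in enumerate(gap_rows):
        c0 = min(col_spans[g][0], col_spans[g + 1][0])
        c1 = max(col_spans[g][1], col_spans[g + 1][1])
        image[r0:r1, c0:c1] = 0.30
        mask[r0:r1, c0:c1] = DISC

    # degeneration: sclerotic endplates border a narrowed disc space
    for g, frac in enumerate(spec.disc_gap_fraction):
        if frac < DEGENERATION_THRESHOLD:
            c0 = min(col_spans[g][0], col_spans[g + 1][0])
            c1 = max(col_spans[g][1], col_spans[g + 1][1])
            above = vert_rows[g][1]
            below = vert_rows[g + 1][0]
            image[max(above - 2, 0):above, c0:c1] = 0.88
            image[below:below + 2, c0:c1] = 0.88

    # interbody fusion: radiodense bony bridge filling the disc space
    for a, b in sorted(spec.fused_levels):
        g = min(a, b)
        r0, r1 = gap_rows[g]
        c0 = min(col_spans[g][0], col_spans[g + 1][0])
        c1 = max(col_spans[g][1], col_spans[g + 1][1])
        image[r0:r1, c0:c1] = 0.78
        mask[r0:r1, c0:c1] = VERTEBRA

    # instrumentation: screws flank the vertebra, rod runs vertically
    screws, rod_pixels = _hardware_pixels(spec, geometry)
    for pixels in screws.values():
        for r, c in pixels:
            image[r, c] = 0.98
            mask[r, c] = INSTRUMENTATION
    for r, c in rod_pixels:
        image[r, c] = 0.95
        mask[r, c] = INSTRUMENTATION

    report, regions = render_report(spec, rng, geometry=geometry)

    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)
    image = np.clip(image, 0.0, 1.0)

    return PhantomSample(image=image, mask=mask, report=report,
                         concept_regions=regions, labels=spec.labels,
                         patient_id="", view=spec.view, spec=spec)


# ---------------------------------------------------------------------------
# dataset-level generation

@dataclass(frozen=True)
class SamplerParams:
    """Prevalences and geometry used when sampling per-patient findings."""
    image_size: int = 64
    p_instrumentation: float = 0.4
    p_degeneration: float = 0.5
    p_fusion: float = 0.25
    noise_sd: float = 0.02
    jitter: float = 0.5
    unique_findings: bool = False   # force distinct finding configurations


def _sample_findings(rng: np.random.Generator, n_vert: int, params: SamplerParams):
    gaps = np.ones(n_vert - 1)
    if rng.random() < params.p_degeneration:
        k = rng.integers(1, 3)
        # degeneration favors the lower lumbar levels
        weights = np.arange(1, n_vert) ** 1.5
        idx = rng.choice(n_vert - 1, size=min(k, n_vert - 1), replace=False,
                         p=weights / weights.sum())
        for g in idx:
            gaps[g] = rng.uniform(0.25, 0.5)
    instrumented: frozenset[int] = frozenset()
    fused: frozenset[tuple[int, int]] = frozenset()
    if rng.random() < params.p_instrumentation:
        start = int(rng.integers(0, n_vert - 1))
        length = int(rng.integers(2, min(4, n_vert - start) + 1))
        instrumented = frozenset(range(start, start + length))
    if rng.random() < params.p_fusion:
        if instrumented:
            levels = sorted(instrumented)
            a = levels[int(rng.integers(0, len(levels) - 1))]
        else:
            a = int(rng.integers(0, n_vert - 1))
        fused = frozenset({(a, a + 1)})
    return tuple(gaps), instrumented, fused


def generate_dataset(n_patients: int, images_per_patient: int,
                     params: SamplerParams | None = None,
                     seed: int = 0, n_vertebrae: int = 5) -> list[PhantomSample]:
    """Generate a patient-grouped phantom dataset.

    Findings are sampled once per patient and shared across that patient's
    views (alternating AP/lateral), so images of one patient are correlated
    — the property patient-level splitting protects against.  Fully
    deterministic under ``seed``.
    """
    if n_patients < 1 or images_per_patient < 1:
        raise ValueError("n_patients and images_per_patient must be >= 1")
    params = params or SamplerParams()
    rng = np.random.default_rng(seed)
    samples: list[PhantomSample] = []
    seen_configs: set[tuple] = set()
    for p in range(n_patients):
        for _ in range(1000):
            gaps, instrumented, fused = _sample_findings(rng, n_vertebrae, params)
            # semantic identity: which levels are degenerate, not the exact widths
            degen_levels = tuple(g < DEGENERATION_THRESHOLD for g in gaps)
            config = (degen_levels, instrumented, tuple(sorted(fused)))
            if not params.unique_findings or config not in seen_configs:
                break
        else:  # pragma: no cover - config space far exceeds any tested n
            raise RuntimeError("could not sample distinct findings")
        seen_configs.add(config)
        pid = f"P{p:04d}"
        for v in range(images_per_patient):
            view = "AP" if v % 2 == 0 else "lateral"
            spec = PhantomSpec(
                image_height=params.image_size, image_width=params.image_size,
                n_vertebrae=n_vertebrae, disc_gap_fraction=gaps,
                instrumented_levels=instrumented, fused_levels=fused,
                noise_sd=params.noise_sd, jitter=params.jitter,
                seed=int(rng.integers(0, 2**31 - 1)), view=view)
            sample = make_phantom(spec)
            sample.patient_id = pid
            samples.append(sample)
    return samples


def patient_split(samples: list[PhantomSample],
                  ratios: tuple[float, float, float] = (0.7, 0.1, 0.2),
                  seed: int = 0) -> SplitManifest:
    """Leakage-free patient-level split.

    Patients are shuffled by a seeded RNG; each split receives
    floor(ratio * P) patients and remainder patients go to train.  When a
    nonzero-ratio split would receive 0 patients and there are at least as
    many patients as nonzero splits, each such split gets one patient first.
    """
    if any(r < 0 for r in ratios) or not np.isclose(sum(ratios), 1.0):
        raise ValueError("ratios must be nonnegative and sum to 1")
    patients = sorted({s.patient_id for s in samples})
    P = len(patients)
    n_nonzero = sum(r > 0 for r in ratios)
    if P < n_nonzero:
        raise ValueError(f"{P} patients cannot cover {n_nonzero} nonzero splits")
    order = list(np.random.default_rng(seed).permutation(patients))
    counts = [int(np.floor(r * P)) if r > 0 else 0 for r in ratios]
    for i, r in enumerate(ratios):
        if r > 0 and counts[i] == 0:
            counts[i] = 1
    while sum(counts) > P:      # minimum-one bumps may overshoot; shrink train
        counts[int(np.argmax(counts))] -= 1
    counts[0] += P - sum(counts)    # remainder to train
    train = sorted(order[:counts[0]])
    val = sorted(order[counts[0]:counts[0] + counts[1]])
    test = sorted(order[counts[0] + counts[1]:counts[0] + counts[1] + counts[2]])
    return SplitManifest(train=train, val=val, test=test, ratios=tuple(ratios))


# ---------------------------------------------------------------------------
# on-disk format: PNG images/masks + JSON-lines manifest

def write_dataset(samples: list[PhantomSample], out_dir: str | Path) -> Path:
    from PIL import Image

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.jsonl"
    with open(manifest_path, "w") as fh:
        for i, s in enumerate(samples):
            img_rel = f"images/{i:05d}.png"
            mask_rel = f"masks/{i:05d}.png"
            Image.fromarray((s.image * 255).round().astype(np.uint8), "L").save(out / img_rel)
            Image.fromarray(s.mask.astype(np.uint8), "L").save(out / mask_rel)
            fh.write(json.dumps({
                "image_path": img_rel, "mask_path": mask_rel,
                "report": s.report, "labels": s.labels,
                "patient_id": s.patient_id, "view": s.view,
            }) + "\n")
    return manifest_path


def load_manifest(manifest_path: str | Path) -> list[PhantomSample]:
    from PIL import Image

    root = Path(manifest_path).parent
    samples = []
    with open(manifest_path) as fh:
        for line in fh:
            d = json.loads(line)
            image = np.asarray(Image.open(root / d["image_path"]), dtype=float) / 255.0
            mask = np.asarray(Image.open(root / d["mask_path"]), dtype=np.int64)
            samples.append(PhantomSample(
                image=image, mask=mask, report=d["report"], concept_regions={},
                labels=d["labels"], patient_id=d["patient_id"], view=d["view"]))
    return samples
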