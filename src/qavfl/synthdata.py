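"""Synthetic multimodal glaucoma cohorts.

Generates aligned triples of (clinical note, fundus-like image, intraocular
pressure series) driven by a single latent severity per patient, then
partitions them *vertically* across ten clients: clients 1-3 hold text,
4-6 images, 7-9 signals, and client 10 is the integration node that holds
no raw data at all.

The image generator is a parametric optic-disc/optic-cup renderer in which
the cup-to-disc ratio (CDR) is a linear function of severity -- CDR is the
clinically graded feature for glaucoma, so it is the severity carrier for
the image modality.  Notes are assembled from a fixed template grammar with
severity-stratified symptom lexicons, and IOP series are a diurnal sinusoid
on a severity-elevated baseline with AR(1) measurement noise.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage, stats

__all__ = [
    "SynthConfig",
    "PatientRecord",
    "VerticalPartition",
    "ClientView",
    "DEFAULT_ROLES",
    "SOURCE_DATASET_COUNTS",
    "generate_cohort",
    "render_fundus",
    "measure_cdr",
    "generate_note",
    "generate_iop_series",
    "partition_vertical",
    "write_cohort",
    "read_cohort",
]

#: Sample counts of the three public fundus collections the emulated cohort
#: mirrors (SMDG-19, HiGAN-CNN, ONH Fundus); their sum fixes the default
#: cohort size of 2850 with 1380 glaucoma-positive / 1470 negative cases.
SOURCE_DATASET_COUNTS = {"SMDG-19": 650, "HiGAN-CNN": 1700, "ONH-Fundus": 500}

#: Default positive/negative case counts of the emulated study cohort.
COHORT_POSITIVES = 1380
COHORT_NEGATIVES = 1470
COHORT_TOTAL = COHORT_POSITIVES + COHORT_NEGATIVES


class InvalidConfigError(ValueError):
    """Raised for degenerate generator configurations."""


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic cohort generator.

    Defaults emulate the study cohort: 2850 patients with a 1380/1470
    positive/negative balance, 224 px fundus renders, 96-step IOP series
    covering 48 h at 30-min sampling (two diurnal cycles).
    """

    n: int = COHORT_TOTAL
    pos_fraction: float = COHORT_POSITIVES / COHORT_TOTAL
    image_size: int = 224
    signal_length: int = 96
    cdr_range: tuple[float, float] = (0.3, 0.8)
    iop_baseline: float = 14.0          # mmHg, healthy resting pressure
    iop_baseline_sd: float = 2.5        # between-patient baseline spread
    iop_severity_gain: float = 8.0      # mmHg added per unit severity
    diurnal_cycles: float = 2.0         # sinusoid cycles over the series
    diurnal_amplitude: float = 2.0      # mmHg
    severity_threshold: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n < 2:
            raise InvalidConfigError(f"need n >= 2, got {self.n}")
        if not 0.0 < self.pos_fraction < 1.0:
            raise InvalidConfigError(
                f"pos_fraction must lie in (0, 1), got {self.pos_fraction}"
            )
        n_pos = int(round(self.n * self.pos_fraction))
        if n_pos < 1 or n_pos > self.n - 1:
            raise InvalidConfigError("pos_fraction degenerate for this n")
        lo, hi = self.cdr_range
        if not (0.0 < lo < hi < 1.0):
            raise InvalidConfigError(f"cdr_range must satisfy 0 < lo < hi < 1, got {self.cdr_range}")
        if self.image_size < 64:
            raise InvalidConfigError("image_size must be >= 64")
        if self.signal_length < 16:
            raise InvalidConfigError("signal_length must be >= 16")


@dataclass
class PatientRecord:
    """One aligned multimodal sample; every field is always populated
    (modality missingness is applied downstream, never at generation)."""

    patient_id: str
    note: str
    image: np.ndarray       # H x W x 3 in [0, 1]
    signal: np.ndarray      # length-L IOP series, mmHg
    label: int              # 1 = glaucoma
    severity: float         # latent, in [0, 1]


@dataclass
class ClientView:
    """What a single client is allowed to see: its own modality payloads
    plus the shared entity alignment (patient ids and labels)."""

    client_id: int
    modality: str | None            # None for the integration node
    patient_ids: list[str]
    labels: np.ndarray
    data: list | None               # raw payloads; None for client 10


@dataclass
class VerticalPartition:
    client_views: dict[int, ClientView]
    integration_client: int


#: Fixed modality assignment of the ten-client federation.
DEFAULT_ROLES: dict[int, str | None] = {
    1: "text", 2: "text", 3: "text",
    4: "image", 5: "image", 6: "image",
    7: "signal", 8: "signal", 9: "signal",
    10: None,
}

_VALID_MODALITIES = {"text", "image", "signal", None}


# ---------------------------------------------------------------------------
# note grammar

# Slot -> (glaucomatous terms, healthy terms).  Single-word fillers keep the
# vocabulary closed and make term-frequency audits trivial.
_NOTE_SLOTS: list[tuple[tuple[str, ...], tuple[str, ...]]] = [
    (("blurring", "halos", "photophobia", "ache"),
     ("clarity", "comfort", "brightness", "sharpness")),
    (("headache", "nausea", "glare", "dimness"),
     ("ease", "stability", "vitality", "wellness")),
    (("cupping", "excavation", "notching", "pallor"),
     ("pink", "healthy", "distinct", "crisp")),
    (("thinning", "hemorrhage", "asymmetry", "atrophy"),
     ("intact", "flat", "symmetric", "unremarkable")),
    (("elevated", "raised", "high", "increased"),
     ("normal", "soft", "stable", "low")),
    (("constricted", "scotoma", "arcuate", "defect"),
     ("full", "complete", "preserved", "clear")),
    (("narrowing", "loss", "depression", "restriction"),
     ("steady", "broad", "uniform", "consistent")),
    (("suspicious", "asymmetric", "progressive", "worsening"),
     ("benign", "symmetrical", "unchanged", "improving")),
    (("drops", "laser", "surgery", "medication"),
     ("monitoring", "discharge", "spectacles", "lubricants")),
    (("urgent", "referral", "escalation", "treatment"),
     ("routine", "review", "observation", "reassurance")),
]

_NOTE_TEMPLATE = (
    "patient reports {0} and {1} . optic disc examination shows {2} with {3} . "
    "intraocular pressure appears {4} . visual field testing indicates {5} "
    "with {6} . retinal nerve fiber layer looks {7} . recommend {8} . "
    "plan is {9} ."
)

#: Flat set of glaucoma-indicating terms, for frequency audits.
GLAUCOMATOUS_TERMS = frozenset(t for glauc, _ in _NOTE_SLOTS for t in glauc)
#: Flat set of healthy-indicating terms.
HEALTHY_TERMS = frozenset(t for _, healthy in _NOTE_SLOTS for t in healthy)
#: Full closed vocabulary the generator can emit (fillers plus template words).
NOTE_VOCABULARY = (
    GLAUCOMATOUS_TERMS
    | HEALTHY_TERMS
    | frozenset(
        w for w in _NOTE_TEMPLATE.replace(".", " ").split()
        if not w.startswith("{")
    )
)


def generate_note(severity: float, seed: int) -> str:
    """Assemble a clinical note from the template grammar.

    Each slot draws a glaucomatous filler with probability equal to
    ``severity`` (healthy filler otherwise), so severity 1 yields a fully
    glaucomatous narrative and severity 0 a fully healthy one, with
    binomial overlap in between.
    """
    if not 0.0 <= severity <= 1.0:
        raise ValueError(f"severity must lie in [0, 1], got {severity}")
    rng = np.random.default_rng(seed)
    fillers = []
    for glauc, healthy in _NOTE_SLOTS:
        pool = glauc if rng.random() < severity else healthy
        fillers.append(pool[rng.integers(len(pool))])
    return _NOTE_TEMPLATE.format(*fillers)


# ---------------------------------------------------------------------------
# fundus renderer

def render_fundus(
    severity: float,
    size: int,
    seed: int,
    cdr_range: tuple[float, float] = (0.3, 0.8),
    return_masks: bool = False,
):
    """Render a parametric fundus-like image.

    A bright optic disc ellipse with an inner, brighter optic cup is drawn
    on a reddish retinal background; dark vessel arcs and Gaussian pixel
    noise are overlaid.  The cup-to-disc ratio is
    ``cdr_low + severity * (cdr_high - cdr_low)`` by construction.

    Parameters
    ----------
    return_masks
        If True, also return the boolean disc and cup masks, from which the
        realized CDR can be re-measured as ``sqrt(area_cup / area_disc)``.
    """
    if not 0.0 <= severity <= 1.0:
        raise ValueError(f"severity must lie in [0, 1], got {severity}")
    if size < 64:
        raise ValueError(f"size must be >= 64, got {size}")
    lo, hi = cdr_range
    cdr = lo + severity * (hi - lo)
    rng = np.random.default_rng(seed)

    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    cx = size * (0.5 + rng.uniform(-0.05, 0.05))
    cy = size * (0.5 + rng.uniform(-0.05, 0.05))
    # ONH-centered framing: the disc spans a sizeable part of the crop, as
    # in optic-nerve-head fundus datasets annotated for CDR grading
    r_disc = size * 0.22 * (1.0 + rng.uniform(-0.08, 0.08))
    aspect = 1.0 + rng.uniform(-0.08, 0.08)   # shared by disc and cup
    a_d, b_d = r_disc, r_disc * aspect
    a_c, b_c = cdr * a_d, cdr * b_d

    disc_mask = ((xx - cx) / a_d) ** 2 + ((yy - cy) / b_d) ** 2 <= 1.0
    cup_mask = ((xx - cx) / a_c) ** 2 + ((yy - cy) / b_c) ** 2 <= 1.0

    # retinal background with a gentle radial vignette
    rad = np.hypot(xx - size / 2, yy - size / 2) / (size / 2)
    img = np.empty((size, size, 3))
    img[..., 0] = 0.80 - 0.15 * rad
    img[..., 1] = 0.38 - 0.10 * rad
    img[..., 2] = 0.16 - 0.05 * rad

    disc_color = np.array([0.95, 0.78, 0.45])
    cup_color = np.array([1.00, 0.93, 0.70])
    img[disc_mask] = disc_color
    img[cup_mask] = cup_color

    # vessel-like dark arcs: random quadratic Bezier curves
    t = np.linspace(0.0, 1.0, 4 * size)[:, None]
    for _ in range(6):
        p0 = rng.uniform(0, size, 2)
        p1 = rng.uniform(0, size, 2)
        p2 = rng.uniform(0, size, 2)
        curve = (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t**2 * p2
        cols = np.clip(curve[:, 0].astype(int), 0, size - 1)
        rows = np.clip(curve[:, 1].astype(int), 0, size - 1)
        width = max(1, size // 112)
        for dr in range(-width, width + 1):
            rr = np.clip(rows + dr, 0, size - 1)
            img[rr, cols] *= 0.55
    # acquisition variability: exposure gain and defocus blur, as in mixed
    # clinical fundus collections; applied to pixels only, never the masks
    img *= rng.uniform(0.8, 1.2)
    blur = rng.uniform(0.5, 1.5) * size / 64.0
    img = ndimage.gaussian_filter(img, sigma=(blur, blur, 0.0))
    img += rng.normal(0.0, 0.02, img.shape)
    np.clip(img, 0.0, 1.0, out=img)

    if return_masks:
        return img, disc_mask, cup_mask
    return img


def measure_cdr(disc_mask: np.ndarray, cup_mask: np.ndarray) -> float:
    """Realized cup-to-disc ratio from rendered masks (area-based)."""
    return float(np.sqrt(cup_mask.sum() / disc_mask.sum()))


# ---------------------------------------------------------------------------
# IOP simulator

def generate_iop_series(
    severity: float,
    length: int,
    seed: int,
    baseline: float = 14.0,
    baseline_sd: float = 2.5,
    gain: float = 8.0,
    cycles: float = 2.0,
    amplitude: float = 2.0,
) -> np.ndarray:
    """Simulate an intraocular-pressure series (mmHg).

    series = patient baseline + severity * gain + diurnal sinusoid + AR(1)
    noise, clipped to be nonnegative.  The patient's resting baseline is
    drawn N(baseline, baseline_sd^2) -- healthy IOP spans roughly 10-21
    mmHg between individuals, which is what keeps mean pressure an
    informative but imperfect severity marker.  ``cycles`` counts full
    diurnal periods over the series (default 2: a 48-h recording at 30-min
    sampling).
    """
    if not 0.0 <= severity <= 1.0:
        raise ValueError(f"severity must lie in [0, 1], got {severity}")
    if length < 16:
        raise ValueError(f"length must be >= 16, got {length}")
    rng = np.random.default_rng(seed)
    baseline = rng.normal(baseline, baseline_sd)
    t = np.arange(length, dtype=np.float64)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    diurnal = amplitude * np.sin(2.0 * np.pi * cycles * t / length + phase)

    rho, noise_sd = 0.7, 0.5
    eps = rng.normal(0.0, noise_sd, length)
    noise = np.empty(length)
    noise[0] = eps[0] / np.sqrt(1.0 - rho**2)   # stationary start
    for i in range(1, length):
        noise[i] = rho * noise[i - 1] + eps[i]

    series = baseline + severity * gain + diurnal + noise
    return np.maximum(series, 0.0)


# ---------------------------------------------------------------------------
# cohort generation

def generate_cohort(config: SynthConfig) -> list[PatientRecord]:
    """Generate an aligned multimodal cohort.

    Exactly ``round(n * pos_fraction)`` records are positive.  Severity is
    drawn from class-conditional truncated normals (positives: mean 0.7 on
    [threshold, 1]; negatives: mean 0.3 on [0, threshold)), both sd 0.12, so
    ``label == 1  iff  severity >= threshold`` holds exactly while the
    modality features of the two classes overlap through their noise.

    All three modalities of a record derive from the same severity draw.
    Per-record randomness comes from children of a single seed sequence, so
    a fixed config reproduces the cohort byte for byte.
    """
    config.validate()
    n_pos = int(round(config.n * config.pos_fraction))

    root = np.random.SeedSequence(config.seed)
    label_seed, sev_seed, *record_seeds = root.spawn(config.n + 2)

    labels = np.zeros(config.n, dtype=int)
    labels[:n_pos] = 1
    np.random.default_rng(label_seed).shuffle(labels)

    thr, sd = config.severity_threshold, 0.12
    sev_rng = np.random.default_rng(sev_seed)

    def _trunc(mean, low, high, n_draw):
        a, b = (low - mean) / sd, (high - mean) / sd
        return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n_draw, random_state=sev_rng)

    severities = np.where(
        labels == 1,
        _trunc(0.7, thr, 1.0, config.n),
        _trunc(0.3, 0.0, thr - 1e-9, config.n),
    )

    records = []
    for i in range(config.n):
        sub = record_seeds[i].generate_state(3)
        note = generate_note(float(severities[i]), int(sub[0] % (2**31)))
        image = render_fundus(
            float(severities[i]), config.image_size, int(sub[1] % (2**31)),
            cdr_range=config.cdr_range,
        )
        signal = generate_iop_series(
            float(severities[i]), config.signal_length, int(sub[2] % (2**31)),
            baseline=config.iop_baseline, baseline_sd=config.iop_baseline_sd,
            gain=config.iop_severity_gain,
            cycles=config.diurnal_cycles, amplitude=config.diurnal_amplitude,
        )
        records.append(
            PatientRecord(
                patient_id=f"P{i:05d}",
                note=note,
                image=image,
                signal=signal,
                label=int(labels[i]),
                severity=float(severities[i]),
            )
        )
    return records


def partition_vertical(
    cohort: list[PatientRecord],
    roles: dict[int, str | None] | None = None,
) -> VerticalPartition:
    """Split a cohort vertically across clients.

    Every client sees every patient (same id order, same labels) but only
    its own modality's raw payloads; the integration node sees none.
    """
    roles = dict(DEFAULT_ROLES if roles is None else roles)
    for cid, modality in roles.items():
        if modality not in _VALID_MODALITIES:
            raise InvalidConfigError(f"unknown modality {modality!r} for client {cid}")
    integration = [cid for cid, m in roles.items() if m is None]
    if len(integration) != 1:
        raise InvalidConfigError("exactly one integration client required")

    patient_ids = [r.patient_id for r in cohort]
    labels = np.array([r.label for r in cohort], dtype=int)
    payload = {
        "text": [r.note for r in cohort],
        "image": [r.image for r in cohort],
        "signal": [r.signal for r in cohort],
    }
    views = {}
    for cid, modality in roles.items():
        views[cid] = ClientView(
            client_id=cid,
            modality=modality,
            patient_ids=list(patient_ids),
            labels=labels.copy(),
            data=None if modality is None else list(payload[modality]),
        )
    return VerticalPartition(client_views=views, integration_client=integration[0])


# ---------------------------------------------------------------------------
# on-disk formats

def write_cohort(cohort: list[PatientRecord], outdir: str | Path) -> None:
    """Write PNG images + manifest CSV, notes JSONL and signals CSV."""
    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)

    with open(outdir / "manifest.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "path", "label"])
        for r in cohort:
            rel = f"images/{r.patient_id}.png"
            Image.fromarray((r.image * 255).round().astype(np.uint8)).save(outdir / rel)
            writer.writerow([r.patient_id, rel, r.label])

    with open(outdir / "notes.jsonl", "w") as fh:
        for r in cohort:
            fh.write(json.dumps({"patient_id": r.patient_id, "note": r.note, "label": r.label}) + "\n")

    L = len(cohort[0].signal)
    with open(outdir / "signals.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id"] + [f"v{i}" for i in range(L)] + ["label"])
        for r in cohort:
            writer.writerow([r.patient_id] + [f"{v:.6f}" for v in r.signal] + [r.label])

    with open(outdir / "severity.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "severity"])
        for r in cohort:
            writer.writerow([r.patient_id, f"{r.severity:.8f}"])


def read_cohort(outdir: str | Path) -> list[PatientRecord]:
    """Read a cohort previously written by :func:`write_cohort`."""
    outdir = Path(outdir)
    with open(outdir / "manifest.csv", newline="") as fh:
        manifest = list(csv.DictReader(fh))
    notes = {}
    with open(outdir / "notes.jsonl") as fh:
        for line in fh:
            row = json.loads(line)
            notes[row["patient_id"]] = row["note"]
    signals = {}
    with open(outdir / "signals.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            vals = [float(v) for k, v in row.items() if k.startswith("v")]
            signals[row["patient_id"]] = np.array(vals)
    severities = {}
    sev_path = outdir / "severity.csv"
    if sev_path.exists():
        with open(sev_path, newline="") as fh:
            for row in csv.DictReader(fh):
                severities[row["patient_id"]] = float(row["severity"])

    records = []
    for row in manifest:
        pid = row["patient_id"]
        img = np.asarray(Image.open(outdir / row["path"]), dtype=np.float64) / 255.0
        records.append(
            PatientRecord(
                patient_id=pid,
                note=notes[pid],
                image=img,
                signal=signals[pid],
                label=int(row["label"]),
                severity=severities.get(pid, float("nan")),
            )
        )
    return records
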