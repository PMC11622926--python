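"""Synthetic study data: Cleveland-style tables, fused vital-sign streams,
and class-textured grayscale images.

The tabular generator emulates the 13-attribute heart-disease schema (age,
sex, chest pain type, resting blood pressure, cholesterol, fasting blood
sugar, resting ECG, maximum heart rate, exercise angina, ST depression,
slope, number of major vessels, thalassemia) with a binary diagnosis target
drawn from a logistic model over a planted subset of informative columns.
Only the schema and rule structure are emulated; no claim of distributional
fidelity to any clinical cohort is made.

The sensor generator emits fused wearable observations (heart rate, PR
interval, body temperature, blood pressure, SpO2) labelled abnormal (1) when
any vital-sign rule fires:

* heart rate below 60 bpm (bradycardia) or above 100 bpm (tachycardia);
* PR interval above 0.2 s (atrioventricular block);
* body temperature above 100.4 F (fever);
* systolic pressure >= 130 mmHg or diastolic >= 81 mmHg (high blood
  pressure; 120-129 systolic with diastolic <= 80 counts as elevated but
  still labels 0);
* SpO2 below 95 percent.

Boundary equality (exactly 60/100 bpm, 0.2 s, 100.4 F, 95 percent) labels 0:
the rules fire strictly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import ValidationError
from .preprocessing import CONTINUOUS, DISCRETE, FeatureTable, write_fused_csv

__all__ = [
    "CLEVELAND_COLUMNS",
    "DEFAULT_EFFECTS",
    "SynthTableSpec",
    "SensorRecord",
    "generate_cleveland_like",
    "generate_sensor_stream",
    "label_sensor_record",
    "fuse_records_to_csv",
    "generate_echo_images",
]

#: (name, kind, low, high) — discrete columns draw integer codes in [low, high]
CLEVELAND_COLUMNS = [
    ("age", CONTINUOUS, 29, 77),
    ("sex", DISCRETE, 0, 1),
    ("cp", DISCRETE, 0, 3),
    ("trestbps", CONTINUOUS, 90, 200),
    ("chol", CONTINUOUS, 120, 420),
    ("fbs", DISCRETE, 0, 1),
    ("restecg", DISCRETE, 0, 1),
    ("thalach", CONTINUOUS, 70, 210),
    ("exang", DISCRETE, 0, 1),
    ("oldpeak", CONTINUOUS, 0.0, 6.2),
    ("slope", DISCRETE, 0, 2),
    ("ca", DISCRETE, 0, 3),
    ("thal", DISCRETE, 0, 2),
]

#: default planted signal: four informative columns, logistic effect sizes on
#: the standardized column values; sized so the design's Bayes accuracy is
#: close to 0.95 at the default noise level
DEFAULT_EFFECTS = {"chol": 6.0, "cp": 5.5, "oldpeak": 5.8, "thalach": -5.2}


@dataclass
class SynthTableSpec:
    """Recipe for one synthetic Cleveland-like table."""

    n_samples: int = 350
    effects: dict = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    noise_sd: float = 0.25
    missing_rate: float = 0.02
    prevalence: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        names = {c[0] for c in CLEVELAND_COLUMNS}
        for key in self.effects:
            if key not in names:
                raise ValidationError(f"unknown informative column {key!r}")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValidationError("missing_rate must be in [0, 1)")
        if not (0.0 < self.prevalence < 1.0):
            raise ValidationError("prevalence must be in (0, 1)")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")

    @property
    def informative_indices(self) -> list[int]:
        names = [c[0] for c in CLEVELAND_COLUMNS]
        return sorted(names.index(k) for k in self.effects)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _tune_intercept(signal: np.ndarray, prevalence: float) -> float:
    """Bisect the intercept so mean sigmoid(b0 + signal) == prevalence."""
    lo, hi = -40.0, 40.0
    if _sigmoid(lo + signal).mean() > prevalence or _sigmoid(hi + signal).mean() < prevalence:
        warnings.warn("requested prevalence unreachable; using closest intercept")
        return lo if _sigmoid(lo + signal).mean() > prevalence else hi
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if _sigmoid(mid + signal).mean() < prevalence:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_cleveland_like(
    spec: SynthTableSpec, return_probabilities: bool = False
):
    """Draw a Cleveland-like table with a planted logistic signal.

    Continuous columns are uniform over plausible clinical ranges, discrete
    columns uniform over their code sets. The label is Bernoulli with
    P(y=1) = sigmoid(b0 + sum_j effect_j * z_j + noise), z_j the standardized
    informative columns, b0 tuned to the target prevalence. Missing cells are
    placed uniformly at ``missing_rate``. Pure function of (spec, seed).

    With ``return_probabilities`` the per-row class-1 probabilities are also
    returned (useful for computing the design's Bayes accuracy).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    names = [c[0] for c in CLEVELAND_COLUMNS]
    kinds = [c[1] for c in CLEVELAND_COLUMNS]
    values = np.empty((n, len(CLEVELAND_COLUMNS)))
    for j, (name, kind, lo, hi) in enumerate(CLEVELAND_COLUMNS):
        if kind == DISCRETE:
            values[:, j] = rng.integers(lo, hi + 1, size=n)
        else:
            values[:, j] = rng.uniform(lo, hi, size=n)

    if n == 0:
        table = FeatureTable(names, kinds, values, np.empty(0, dtype=int))
        return (table, np.empty(0)) if return_probabilities else table

    signal = np.zeros(n)
    for name, effect in spec.effects.items():
        col = values[:, names.index(name)]
        sd = col.std(ddof=0)
        z = (col - col.mean()) / sd if sd > 0 else np.zeros(n)
        signal += effect * z
    signal += rng.normal(0.0, spec.noise_sd, size=n)
    b0 = _tune_intercept(signal, spec.prevalence)
    probs = _sigmoid(b0 + signal)
    target = (rng.random(n) < probs).astype(int)

    if spec.missing_rate > 0:
        holes = rng.random(values.shape) < spec.missing_rate
        values = values.copy()
        values[holes] = math.nan

    table = FeatureTable(names, kinds, values, target)
    return (table, probs) if return_probabilities else table


# ---------------------------------------------------------------------------
# fused wearable-sensor records


@dataclass
class SensorRecord:
    """One fused multi-sensor observation with its rule-derived label."""

    heart_rate: float
    pr_interval: float
    temperature: float
    systolic: float
    diastolic: float
    spo2: float
    label: int = 0

    def __post_init__(self) -> None:
        for name in ("heart_rate", "pr_interval", "temperature",
                     "systolic", "diastolic", "spo2"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.spo2 > 100:
            raise ValidationError("spo2 cannot exceed 100 percent")


def label_sensor_record(record: SensorRecord) -> int:
    """1 (abnormal) iff any vital-sign rule fires; rules fire strictly."""
    if record.heart_rate < 60 or record.heart_rate > 100:
        return 1
    if record.pr_interval > 0.2:
        return 1
    if record.temperature > 100.4:
        return 1
    if record.systolic >= 130 or record.diastolic >= 81:
        return 1
    if record.spo2 < 95:
        return 1
    return 0


def _draw_normal_record(rng: np.random.Generator) -> SensorRecord:
    rec = SensorRecord(
        heart_rate=rng.uniform(61, 99),
        pr_interval=rng.uniform(0.12, 0.19),
        temperature=rng.uniform(97.0, 99.8),
        systolic=rng.uniform(100, 128),
        diastolic=rng.uniform(62, 79),
        spo2=rng.uniform(95.5, 99.9),
    )
    rec.label = label_sensor_record(rec)
    return rec


_VIOLATIONS = (
    ("heart_rate", lambda rng: rng.uniform(40, 58) if rng.random() < 0.5
     else rng.uniform(101, 150)),
    ("pr_interval", lambda rng: rng.uniform(0.21, 0.32)),
    ("temperature", lambda rng: rng.uniform(100.6, 104.0)),
    ("systolic", lambda rng: rng.uniform(130, 185)),
    ("spo2", lambda rng: rng.uniform(80, 94.4)),
)


def _draw_abnormal_record(rng: np.random.Generator) -> SensorRecord:
    rec = _draw_normal_record(rng)
    n_rules = 1 + rng.binomial(len(_VIOLATIONS) - 1, 0.2)
    which = rng.choice(len(_VIOLATIONS), size=n_rules, replace=False)
    for i in which:
        name, draw = _VIOLATIONS[i]
        setattr(rec, name, float(draw(rng)))
    rec.label = label_sensor_record(rec)
    return rec


def generate_sensor_stream(
    n: int, abnormal_fraction: float, seed: int = 0
) -> list[SensorRecord]:
    """n fused sensor records, a given fraction violating >= 1 rule.

    Normal records are drawn strictly inside every normal range; abnormal
    records violate at least one threshold. The stored label always equals
    ``label_sensor_record`` reapplied to the values.
    """
    if not (0.0 <= abnormal_fraction <= 1.0):
        raise ValidationError("abnormal_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_abnormal = int(round(n * abnormal_fraction))
    records = [_draw_abnormal_record(rng) for _ in range(n_abnormal)]
    records += [_draw_normal_record(rng) for _ in range(n - n_abnormal)]
    order = rng.permutation(len(records))
    return [records[i] for i in order]


SENSOR_FIELDS = ["heart_rate", "pr_interval", "temperature",
                 "systolic", "diastolic", "spo2"]


def fuse_records_to_csv(records: list[SensorRecord], path) -> None:
    """Write fused records as CSV (6 sensor fields + binary label)."""
    if not records:
        raise ValidationError("record list must be non-empty")
    values = np.array(
        [[getattr(r, f) for f in SENSOR_FIELDS] for r in records], dtype=float
    )
    labels = np.array([r.label for r in records], dtype=int)
    table = FeatureTable(
        list(SENSOR_FIELDS), [CONTINUOUS] * len(SENSOR_FIELDS), values, labels,
        target_name="label",
    )
    write_fused_csv(table, path)


# ---------------------------------------------------------------------------
# synthetic echocardiogram-style images


def generate_echo_images(
    root, n_per_class: int, size: int = 64, seed: int = 0
) -> Path:
    """Write two class folders ("abnormal", "normal") of separable PNGs.

    Synthetic stand-ins for echocardiogram frames: each image is a noisy
    grayscale field with a bright horizontal band whose position and
    brightness depend on the class, so the classes are separable by design.
    """
    from PIL import Image

    if n_per_class < 1:
        raise ValidationError("n_per_class must be >= 1")
    root = Path(root)
    rng = np.random.default_rng(seed)
    # (base intensity, band start fraction, band intensity) per class
    styles = {"abnormal": (150, 0.55, 230), "normal": (90, 0.25, 180)}
    for cls in sorted(styles):
        base, band_at, band_val = styles[cls]
        cdir = root / cls
        cdir.mkdir(parents=True, exist_ok=True)
        for i in range(n_per_class):
            img = rng.normal(base, 25.0, size=(size, size))
            b0 = int(band_at * size)
            img[b0 : b0 + max(2, size // 8), :] = rng.normal(
                band_val, 10.0, size=(max(2, size // 8), size)
            )
            arr = np.clip(img, 0, 255).astype(np.uint8)
            Image.fromarray(arr, mode="L").save(cdir / f"{cls}_{i:04d}.png")
    return root
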