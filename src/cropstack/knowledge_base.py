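"""Per-crop agronomic constraint tables and Gaussian suitability scoring.

The knowledge base stores, for every crop, the mean and standard deviation of
its ideal growing temperature (degrees Celsius) and soil pH.  Suitability of an
observed condition is scored with an unnormalised Gaussian kernel: 1 at the
optimum, decaying with squared distance in units of the crop's tolerance.

Scores are always computed on raw physical values (degrees Celsius, pH units),
never on rescaled features.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import CoverageError, ParseError, ValidationError

__all__ = [
    "CropPhysicsEntry",
    "PhysicsKnowledgeBase",
    "PhysicsScores",
    "CoverageReport",
    "gaussian_score",
    "physics_scores",
    "load_knowledge_base",
    "default_knowledge_base",
    "validate_coverage",
]

_FIELDS = ("label", "mu_temp", "sigma_temp", "mu_ph", "sigma_ph")


@dataclass(frozen=True)
class CropPhysicsEntry:
    """Constraint parameters for one crop: ideal temperature and pH as (mu, sigma)."""

    crop_label: str
    mu_temp: float
    sigma_temp: float
    mu_ph: float
    sigma_ph: float

    def __post_init__(self) -> None:
        if not self.crop_label:
            raise ValidationError("crop_label must be a non-empty string")
        if not np.isfinite([self.mu_temp, self.sigma_temp, self.mu_ph, self.sigma_ph]).all():
            raise ValidationError(f"non-finite parameter for crop {self.crop_label!r}")
        if self.sigma_temp <= 0:
            raise ValidationError(
                f"sigma_temp must be > 0 for crop {self.crop_label!r}, got {self.sigma_temp}"
            )
        if self.sigma_ph <= 0:
            raise ValidationError(
                f"sigma_ph must be > 0 for crop {self.crop_label!r}, got {self.sigma_ph}"
            )
        if not 0.0 <= self.mu_ph <= 14.0:
            raise ValidationError(
                f"mu_ph must lie in [0, 14] for crop {self.crop_label!r}, got {self.mu_ph}"
            )


@dataclass(frozen=True)
class PhysicsScores:
    """Gaussian suitability of one (temperature, pH) observation for one crop."""

    temp_score: float
    ph_score: float


def gaussian_score(value, mu, sigma):
    """Unnormalised Gaussian suitability: exp(-(value - mu)^2 / (2 sigma^2)).

    Equals 1 exactly when ``value == mu`` and decays strictly with
    ``|value - mu|``.  Accepts scalars or numpy arrays (broadcasting applies).

    Raises
    ------
    ValidationError
        If ``sigma`` is not strictly positive.
    """
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValidationError(f"sigma must be > 0, got {sigma}")
    value = np.asarray(value, dtype=float)
    mu = np.asarray(mu, dtype=float)
    out = np.exp(-((value - mu) ** 2) / (2.0 * sigma**2))
    if out.ndim == 0:
        return float(out)
    return out


def physics_scores(temp: float, ph: float, entry: CropPhysicsEntry) -> PhysicsScores:
    """Score a raw (temperature, pH) pair against one crop's optima."""
    return PhysicsScores(
        temp_score=float(gaussian_score(temp, entry.mu_temp, entry.sigma_temp)),
        ph_score=float(gaussian_score(ph, entry.mu_ph, entry.sigma_ph)),
    )


class PhysicsKnowledgeBase:
    """Ordered collection of :class:`CropPhysicsEntry`, keyed by crop label.

    ``class_order`` fixes the column ordering of every probability vector and
    score matrix built from this table; by default it is the sorted label order.
    """

    def __init__(
        self,
        entries: Iterable[CropPhysicsEntry],
        class_order: Sequence[str] | None = None,
    ) -> None:
        entries = list(entries)
        self._entries: dict[str, CropPhysicsEntry] = {}
        for e in entries:
            if e.crop_label in self._entries:
                raise ValidationError(f"duplicate crop label {e.crop_label!r}")
            self._entries[e.crop_label] = e
        if not self._entries:
            raise ValidationError("knowledge base must contain at least one crop")
        if class_order is None:
            class_order = sorted(self._entries)
        else:
            class_order = list(class_order)
            if sorted(class_order) != sorted(self._entries):
                raise ValidationError("class_order must be a permutation of the entry labels")
        self.class_order: list[str] = list(class_order)

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, label: str) -> bool:
        return label in self._entries

    def __iter__(self):
        return (self._entries[lbl] for lbl in self.class_order)

    @property
    def labels(self) -> list[str]:
        return list(self.class_order)

    def entry(self, label: str) -> CropPhysicsEntry:
        try:
            return self._entries[label]
        except KeyError:
            raise CoverageError(f"crop {label!r} not in knowledge base") from None

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(mu_temp, sigma_temp, mu_ph, sigma_ph), each shape (C,), in class_order."""
        es = [self._entries[lbl] for lbl in self.class_order]
        return (
            np.array([e.mu_temp for e in es]),
            np.array([e.sigma_temp for e in es]),
            np.array([e.mu_ph for e in es]),
            np.array([e.sigma_ph for e in es]),
        )

    def score_matrix(self, temp: np.ndarray, ph: np.ndarray) -> np.ndarray:
        """Combined suitability temp_score * ph_score for each sample and crop.

        Parameters are raw physical values, shape (n,).  Returns shape (n, C)
        with columns in ``class_order``; every entry lies in (0, 1].
        """
        temp = np.asarray(temp, dtype=float).reshape(-1, 1)
        ph = np.asarray(ph, dtype=float).reshape(-1, 1)
        mu_t, sg_t, mu_p, sg_p = self.arrays()
        ts = np.exp(-((temp - mu_t) ** 2) / (2.0 * sg_t**2))
        ps = np.exp(-((ph - mu_p) ** 2) / (2.0 * sg_p**2))
        return ts * ps

    def to_dict(self) -> dict:
        return {
            "class_order": self.class_order,
            "crops": [
                {
                    "label": e.crop_label,
                    "mu_temp": e.mu_temp,
                    "sigma_temp": e.sigma_temp,
                    "mu_ph": e.mu_ph,
                    "sigma_ph": e.sigma_ph,
                }
                for e in self
            ],
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def sha256(self) -> str:
        """Hash of the canonical JSON form, recorded in run provenance."""
        canon = json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(canon.encode()).hexdigest()


def _entry_from_record(rec: dict, context: str) -> CropPhysicsEntry:
    missing = [f for f in _FIELDS if f not in rec or rec[f] is None or rec[f] == ""]
    if missing:
        raise ParseError(f"{context}: missing field(s) {missing} in record {rec!r}")
    try:
        return CropPhysicsEntry(
            crop_label=str(rec["label"]),
            mu_temp=float(rec["mu_temp"]),
            sigma_temp=float(rec["sigma_temp"]),
            mu_ph=float(rec["mu_ph"]),
            sigma_ph=float(rec["sigma_ph"]),
        )
    except (TypeError, ValueError) as exc:
        if isinstance(exc, ValidationError):
            raise
        raise ParseError(f"{context}: non-numeric parameter in record {rec!r}") from exc


def load_knowledge_base(
    source: str | Path, class_order: Sequence[str] | None = None
) -> PhysicsKnowledgeBase:
    """Load a knowledge base from a JSON or CSV file.

    JSON layout: ``{"crops": [{"label": ..., "mu_temp": ..., "sigma_temp": ...,
    "mu_ph": ..., "sigma_ph": ...}, ...]}`` with an optional ``class_order``
    key.  CSV layout: one row per crop with those five column headers.
    """
    path = Path(source)
    if not path.exists():
        raise ParseError(f"knowledge base file not found: {path}")
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        lower = {c.lower(): c for c in df.columns}
        missing = [f for f in _FIELDS if f not in lower]
        if missing:
            raise ParseError(f"{path}: missing column(s) {missing}")
        records = [
            {f: row[lower[f]] for f in _FIELDS} for _, row in df.iterrows()
        ]
    else:
        try:
            doc = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path}: invalid JSON ({exc})") from exc
        if not isinstance(doc, dict) or "crops" not in doc:
            raise ParseError(f"{path}: expected a JSON object with a 'crops' list")
        records = doc["crops"]
        if class_order is None:
            class_order = doc.get("class_order")
    entries = [_entry_from_record(rec, str(path)) for rec in records]
    return PhysicsKnowledgeBase(entries, class_order=class_order)


def default_knowledge_base() -> PhysicsKnowledgeBase:
    """The 22-crop illustrative table shipped with the package.

    The per-crop optima are plausible agronomic values, provided so the full
    pipeline runs out of the box; for real analyses supply a curated table.
    """
    with resources.files("cropstack.data").joinpath("default_kb.json").open() as fh:
        doc = json.load(fh)
    entries = [_entry_from_record(rec, "default_kb.json") for rec in doc["crops"]]
    return PhysicsKnowledgeBase(entries)


@dataclass(frozen=True)
class CoverageReport:
    """Labels present in the data but absent from the kb, and vice versa."""

    uncovered: tuple[str, ...]  # in data, not in kb — blocks training
    unused: tuple[str, ...]  # in kb, not in data — harmless

    @property
    def ok(self) -> bool:
        return not self.uncovered


def validate_coverage(kb: PhysicsKnowledgeBase, labels: Iterable[str]) -> CoverageReport:
    """Compare the kb's crops against the labels occurring in a dataset."""
    data_labels = set(labels)
    kb_labels = set(kb.labels)
    return CoverageReport(
        uncovered=tuple(sorted(data_labels - kb_labels)),
        unused=tuple(sorted(kb_labels - data_labels)),
    )


def require_coverage(kb: PhysicsKnowledgeBase, labels: Iterable[str]) -> None:
    report = validate_coverage(kb, labels)
    if not report.ok:
        raise CoverageError(
            f"knowledge base does not cover label(s): {', '.join(report.uncovered)}"
        )
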