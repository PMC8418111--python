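"""Weighted Tanimoto-sum ototoxicity classifier.

A query compound ``c`` is scored against a reference set of known
ototoxins ``O`` and non-ototoxins ``N``::

    Score_c = sum_o alpha_o * T(o, c)  +  sum_n beta_n * T(n, c)

with every ``alpha_o > 0`` and every ``beta_n < 0``, so a positive score
indicates structural proximity to known ototoxins and a negative score
proximity to ear-safe compounds.  The two class sums are accumulated
separately so that a compound's ototoxic and non-ototoxic potential can be
inspected independently.  The decision rule is sign-based: ``score >= 0``
predicts OTOTOXIN (ties resolve toward the hazardous class — for a safety
screen a false alarm is cheaper than a missed ototoxin).

The default weight scheme is class-normalized, ``alpha_o = +1/|O|`` and
``beta_n = -1/|N|``, so each class contributes its *mean* similarity and
heavy over-representation of non-ototoxins in the reference set does not
swamp the ototoxin signal.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .chem_io import Compound, CompoundSet, Label
from .fingerprints import (
    Fingerprint,
    FingerprintParams,
    bulk_tanimoto,
    fingerprint_compounds,
)

__all__ = [
    "WeightMode",
    "WeightScheme",
    "ReferenceModel",
    "ScoredPrediction",
    "ModelBuildError",
    "build_model",
    "score_compound",
    "classify",
    "explain",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = "1"


class WeightMode(enum.Enum):
    CLASS_NORMALIZED = "class-normalized"
    UNIFORM = "uniform"
    CUSTOM = "custom"


class ModelBuildError(ValueError):
    """The reference sets violate a model precondition."""


@dataclass(frozen=True)
class WeightScheme:
    """Per-reference weights for the two class sums.

    CLASS_NORMALIZED: alpha_o = +1/|O|, beta_n = -1/|N| (default).
    UNIFORM: alpha_o = +1, beta_n = -1.
    CUSTOM: caller-supplied per-compound weights (alpha all > 0, beta all < 0).
    """

    mode: WeightMode = WeightMode.CLASS_NORMALIZED
    alpha: Optional[tuple[float, ...]] = None
    beta: Optional[tuple[float, ...]] = None

    def resolve(self, n_oto: int, n_non: int) -> tuple[np.ndarray, np.ndarray]:
        """Concrete weight vectors for reference sets of the given sizes."""
        if self.mode is WeightMode.CLASS_NORMALIZED:
            alpha = np.full(n_oto, 1.0 / n_oto)
            beta = np.full(n_non, -1.0 / n_non)
        elif self.mode is WeightMode.UNIFORM:
            alpha = np.full(n_oto, 1.0)
            beta = np.full(n_non, -1.0)
        else:
            if self.alpha is None or self.beta is None:
                raise ValueError("CUSTOM mode requires explicit alpha and beta")
            alpha = np.asarray(self.alpha, dtype=float)
            beta = np.asarray(self.beta, dtype=float)
            if len(alpha) != n_oto or len(beta) != n_non:
                raise ValueError("custom weight lengths do not match class sizes")
        if not (alpha > 0).all():
            raise ValueError("all ototoxin weights must be positive")
        if not (beta < 0).all():
            raise ValueError("all non-ototoxin weights must be negative")
        return alpha, beta


@dataclass(frozen=True)
class ReferenceModel:
    """Immutable trained classifier: fingerprinted reference sets + weights."""

    ototoxins: tuple[Compound, ...]
    non_ototoxins: tuple[Compound, ...]
    oto_fps: tuple[Fingerprint, ...]
    non_fps: tuple[Fingerprint, ...]
    weights: WeightScheme
    fp_params: FingerprintParams
    low_information_ids: tuple[str, ...] = ()

    def _packed(self) -> tuple[np.ndarray, np.ndarray]:
        """Reference fingerprints packed to uint64 words, cached lazily so
        screening thousands of queries packs each reference set once."""
        cached = getattr(self, "_packed_cache", None)
        if cached is None:
            from .fingerprints import pack_bits

            cached = (pack_bits(self.oto_fps), pack_bits(self.non_fps))
            object.__setattr__(self, "_packed_cache", cached)
        return cached

    @property
    def n_oto(self) -> int:
        return len(self.ototoxins)

    @property
    def n_non(self) -> int:
        return len(self.non_ototoxins)

    def resolved_weights(self) -> tuple[np.ndarray, np.ndarray]:
        return self.weights.resolve(self.n_oto, self.n_non)

    def training_smiles(self) -> frozenset[str]:
        cached = getattr(self, "_smiles_cache", None)
        if cached is None:
            cached = frozenset(
                c.smiles_canonical for c in self.ototoxins + self.non_ototoxins
            )
            object.__setattr__(self, "_smiles_cache", cached)
        return cached

    def digest(self) -> str:
        import hashlib

        h = hashlib.sha1()
        for c in self.ototoxins + self.non_ototoxins:
            h.update(c.smiles_canonical.encode())
            h.update(c.label.value.encode())
        h.update(self.weights.mode.value.encode())
        h.update(self.fp_params.digest().encode())
        return h.hexdigest()[:12]


@dataclass(frozen=True)
class ScoredPrediction:
    """Score, decision and per-reference breakdown for one query."""

    compound_id: str
    score: float
    predicted_label: Label
    oto_sum: float
    non_oto_sum: float
    # (reference id, reference class, similarity, weighted contribution)
    top_neighbors: tuple[tuple[str, Label, float, float], ...] = ()
    in_training_set: bool = False
    low_information: bool = False


def build_model(
    ototoxins: CompoundSet,
    non_ototoxins: CompoundSet,
    weights: WeightScheme | None = None,
    fp_params: FingerprintParams | None = None,
) -> ReferenceModel:
    """Fingerprint the reference sets and assemble an immutable model.

    Raises :class:`ModelBuildError` if a class is empty, a label is
    inconsistent with its role, or a structure appears in both classes —
    reference-set hygiene failures are a known source of bad ototoxicity
    predictions and are never ignored.
    """
    if weights is None:
        weights = WeightScheme()
    if fp_params is None:
        fp_params = FingerprintParams()
    if len(ototoxins) == 0 or len(non_ototoxins) == 0:
        raise ModelBuildError("both reference classes must be non-empty")
    for c in ototoxins:
        if c.label is Label.NON_OTOTOXIN:
            raise ModelBuildError(
                f"compound {c.id!r} labeled non-ototoxin in the ototoxin set"
            )
    for c in non_ototoxins:
        if c.label is Label.OTOTOXIN:
            raise ModelBuildError(
                f"compound {c.id!r} labeled ototoxin in the non-ototoxin set"
            )
    overlap = set(ototoxins.canonical_smiles()) & set(
        non_ototoxins.canonical_smiles()
    )
    if overlap:
        offenders = sorted(
            c.id for c in list(ototoxins) + list(non_ototoxins)
            if c.smiles_canonical in overlap
        )
        raise ModelBuildError(
            f"structures present in both classes: {', '.join(offenders)}"
        )
    # validates sizes and sign conventions early
    weights.resolve(len(ototoxins), len(non_ototoxins))

    oto_fps, low_o = fingerprint_compounds(ototoxins, fp_params)
    non_fps, low_n = fingerprint_compounds(non_ototoxins, fp_params)
    return ReferenceModel(
        ototoxins=tuple(ototoxins),
        non_ototoxins=tuple(non_ototoxins),
        oto_fps=tuple(oto_fps),
        non_fps=tuple(non_fps),
        weights=weights,
        fp_params=fp_params,
        low_information_ids=tuple(low_o + low_n),
    )


def classify(score: float) -> Label:
    """Sign rule: score >= 0 -> OTOTOXIN, score < 0 -> NON_OTOTOXIN."""
    if not math.isfinite(score):
        raise ValueError(f"non-finite score: {score!r}")
    return Label.OTOTOXIN if score >= 0 else Label.NON_OTOTOXIN


def score_compound(
    query: Compound,
    model: ReferenceModel,
    k_neighbors: int = 5,
) -> ScoredPrediction:
    """Score one query against the model.

    The ototoxin and non-ototoxin sums are accumulated separately and then
    added, so each class's evidence is reported independently.
    ``top_neighbors`` holds the ``k_neighbors`` most similar references from
    each class.  A query structurally identical to a reference is scored
    normally but flagged ``in_training_set``.
    """
    from .fingerprints import bulk_tanimoto_packed, compute_fingerprint

    qfp, low_info = compute_fingerprint(query, model.fp_params)
    alpha, beta = model.resolved_weights()

    packed_oto, packed_non = model._packed()
    t_oto = bulk_tanimoto_packed(qfp, packed_oto)
    t_non = bulk_tanimoto_packed(qfp, packed_non)
    oto_sum = float(alpha @ t_oto)
    non_oto_sum = float(beta @ t_non)
    score = oto_sum + non_oto_sum

    def top_k(
        comps: tuple[Compound, ...], sims: np.ndarray, w: np.ndarray, lab: Label
    ) -> list[tuple[str, Label, float, float]]:
        rows = [
            (c.id, lab, float(s), float(wi * s))
            for c, s, wi in zip(comps, sims, w)
        ]
        rows.sort(key=lambda r: (-abs(r[3]), r[0]))
        return rows[:k_neighbors]

    neighbors = top_k(model.ototoxins, t_oto, alpha, Label.OTOTOXIN) + top_k(
        model.non_ototoxins, t_non, beta, Label.NON_OTOTOXIN
    )

    return ScoredPrediction(
        compound_id=query.id,
        score=score,
        predicted_label=classify(score),
        oto_sum=oto_sum,
        non_oto_sum=non_oto_sum,
        top_neighbors=tuple(neighbors),
        in_training_set=query.smiles_canonical in model.training_smiles(),
        low_information=low_info,
    )


def explain(
    prediction: ScoredPrediction, k: int
) -> list[tuple[str, Label, float, float]]:
    """The ``k`` references with largest absolute weighted contribution per
    class, sorted by descending |contribution|, ties broken by id."""
    if k <= 0:
        raise ValueError("k must be positive")
    by_class: dict[Label, list[tuple[str, Label, float, float]]] = {}
    for row in prediction.top_neighbors:
        by_class.setdefault(row[1], []).append(row)
    out: list[tuple[str, Label, float, float]] = []
    for lab in (Label.OTOTOXIN, Label.NON_OTOTOXIN):
        rows = sorted(by_class.get(lab, []), key=lambda r: (-abs(r[3]), r[0]))
        out.extend(rows[:k])
    out.sort(key=lambda r: (-abs(r[3]), r[0]))
    return out


# ---------------------------------------------------------------------------
# model persistence: versioned, self-describing JSON

def _compound_record(c: Compound, fp: Fingerprint) -> dict:
    return {
        "id": c.id,
        "smiles": c.smiles_canonical,
        "label": c.label.value,
        "source": c.source,
        "notes": list(c.notes),
        "fingerprint_hex": fp.to_hex(),
    }


def _compound_from_record(rec: dict, params: FingerprintParams) -> Compound:
    fp = Fingerprint.from_hex(rec["fingerprint_hex"], params)
    return Compound(
        id=rec["id"],
        smiles_raw=rec["smiles"],
        smiles_canonical=rec["smiles"],
        label=Label(rec["label"]),
        source=rec.get("source", "model-file"),
        notes=tuple(rec.get("notes", [])),
        fingerprint=fp,
    )


def save_model(model: ReferenceModel, path) -> None:
    """Serialize the model to a versioned JSON document embedding canonical
    SMILES, labels, weights, fingerprint parameters and the bit vectors
    themselves, so a saved model reproduces its predictions exactly."""
    doc = {
        "format": "ototox-model",
        "version": MODEL_FORMAT_VERSION,
        "fp_params": {
            "algorithm": model.fp_params.algorithm,
            "radius": model.fp_params.radius,
            "n_bits": model.fp_params.n_bits,
            "digest": model.fp_params.digest(),
        },
        "weights": {
            "mode": model.weights.mode.value,
            "alpha": list(model.weights.alpha) if model.weights.alpha else None,
            "beta": list(model.weights.beta) if model.weights.beta else None,
        },
        "digest": model.digest(),
        "low_information_ids": list(model.low_information_ids),
        "ototoxins": [
            _compound_record(c, fp)
            for c, fp in zip(model.ototoxins, model.oto_fps)
        ],
        "non_ototoxins": [
            _compound_record(c, fp)
            for c, fp in zip(model.non_ototoxins, model.non_fps)
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1), encoding="utf-8")


def load_model(path) -> ReferenceModel:
    """Load a model saved by :func:`save_model`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"model file not found: {path}")
    doc = json.loads(path.read_text(encoding="utf-8"))
    if doc.get("format") != "ototox-model":
        raise ValueError(f"{path}: not an ototox model file")
    if doc.get("version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"{path}: unsupported model version {doc.get('version')}")
    p = doc["fp_params"]
    params = FingerprintParams(
        algorithm=p["algorithm"], radius=p["radius"], n_bits=p["n_bits"]
    )
    w = doc["weights"]
    weights = WeightScheme(
        mode=WeightMode(w["mode"]),
        alpha=tuple(w["alpha"]) if w.get("alpha") else None,
        beta=tuple(w["beta"]) if w.get("beta") else None,
    )
    otos = [_compound_from_record(r, params) for r in doc["ototoxins"]]
    nons = [_compound_from_record(r, params) for r in doc["non_ototoxins"]]
    return ReferenceModel(
        ototoxins=tuple(otos),
        non_ototoxins=tuple(nons),
        oto_fps=tuple(c.fingerprint for c in otos),
        non_fps=tuple(c.fingerprint for c in nons),
        weights=weights,
        fp_params=params,
        low_information_ids=tuple(doc.get("low_information_ids", [])),
    )
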