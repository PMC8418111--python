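"""Batch library screening against a trained reference model.

Every parseable library member is scored with the weighted Tanimoto-sum
classifier and the results are ranked by descending score (ties broken by
compound id, so rankings are bit-exactly reproducible).  Compounds that
are structurally identical to a training reference are still scored but
flagged — a screen over a broad drug library is expected to re-discover
its own training ototoxins, and those flags separate re-discoveries from
genuinely novel hits.  Records that fail to parse or fingerprint are
counted and logged, never dropped silently.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .chem_io import Compound, CompoundSet, Label
from .classifier import ReferenceModel, ScoredPrediction, score_compound
from .fingerprints import FingerprintError, IncompatibleFingerprints

__all__ = ["ScreenResult", "screen_library", "screen_result_tsv"]

logger = logging.getLogger("ototox.screening")


@dataclass(frozen=True)
class ScreenResult:
    """Ranked screening output plus run accounting."""

    predictions: tuple[ScoredPrediction, ...]  # descending score, id tiebreak
    n_screened: int
    n_predicted_ototoxin: int
    n_failed: int
    failed_ids: tuple[str, ...]
    model_digest: str
    metadata: dict = field(default_factory=dict)

    def hits(self) -> tuple[ScoredPrediction, ...]:
        """Predictions meeting the ototoxin decision rule (score >= 0)."""
        return tuple(p for p in self.predictions if p.score >= 0)

    def top(self, n: int) -> tuple[ScoredPrediction, ...]:
        """The n highest-scoring compounds regardless of sign."""
        return self.predictions[:n]


def screen_library(
    library: CompoundSet,
    model: ReferenceModel,
    k_neighbors: int = 5,
) -> ScreenResult:
    """Score every library member against the model and rank by score.

    Raises ``ValueError`` on an empty library.  Unfingerprintable members
    are tallied in ``n_failed`` and logged at WARN level.
    """
    if len(library) == 0:
        raise ValueError("cannot screen an empty library")

    predictions: list[ScoredPrediction] = []
    failed: list[str] = []
    for c in library:
        try:
            predictions.append(score_compound(c, model, k_neighbors=k_neighbors))
        except IncompatibleFingerprints:
            raise  # configuration error, not a per-record failure
        except FingerprintError as e:
            failed.append(c.id)
            logger.warning("skipped %s: %s", c.id, e)

    predictions.sort(key=lambda p: (-p.score, p.compound_id))
    n_hits = sum(1 for p in predictions if p.score >= 0)
    return ScreenResult(
        predictions=tuple(predictions),
        n_screened=len(predictions),
        n_predicted_ototoxin=n_hits,
        n_failed=len(failed),
        failed_ids=tuple(failed),
        model_digest=model.digest(),
        metadata={
            "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
            "library": library.name,
        },
    )


def screen_result_tsv(result: ScreenResult, config_echo: str = "") -> str:
    """Ranked TSV with a commented header carrying the model digest, so
    every screen is traceable to the exact model that produced it."""
    lines = [
        f"# ototox screen  model={result.model_digest}",
        f"# n_screened={result.n_screened}"
        f" n_predicted_ototoxin={result.n_predicted_ototoxin}"
        f" n_failed={result.n_failed}",
    ]
    if config_echo:
        lines.append(f"# config: {config_echo}")
    lines.append(
        "rank\tcompound_id\tscore\toto_sum\tnon_oto_sum"
        "\tpredicted_label\tin_training_set\tlow_information"
    )
    for rank, p in enumerate(result.predictions, 1):
        lines.append(
            f"{rank}\t{p.compound_id}\t{p.score:.10g}\t{p.oto_sum:.10g}"
            f"\t{p.non_oto_sum:.10g}\t{p.predicted_label.value}"
            f"\t{int(p.in_training_set)}\t{int(p.low_information)}"
        )
    return "\n".join(lines) + "\n"
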