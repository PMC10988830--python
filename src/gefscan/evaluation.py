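"""Scoring predictions against experimental outcome labels.

A predicted-deleterious variant is confirmed by a loss-of-function or
dominant-negative outcome (a dominant negative is a stronger-than-expected
disruption, not a miss); a predicted-benign variant is confirmed by a
WT-like outcome.  The headline numbers are the deleterious success rate
(confirmed / predicted-deleterious) and the overall accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

__all__ = [
    "EvaluationRecord",
    "AccuracyReport",
    "load_paper_outcomes",
    "compute_accuracy",
]

DELETERIOUS_OUTCOMES = {"loss_of_function", "dominant_negative"}
VALID_OUTCOMES = DELETERIOUS_OUTCOMES | {"wt_like"}


@dataclass(frozen=True)
class EvaluationRecord:
    label: str
    predicted: str  # deleterious | benign
    outcome: str    # loss_of_function | dominant_negative | wt_like

    def __post_init__(self) -> None:
        if self.predicted not in ("deleterious", "benign"):
            raise ValueError(f"invalid prediction {self.predicted!r}")
        if self.outcome not in VALID_OUTCOMES:
            raise ValueError(f"invalid outcome {self.outcome!r}")

    @property
    def match(self) -> bool:
        if self.predicted == "deleterious":
            return self.outcome in DELETERIOUS_OUTCOMES
        return self.outcome == "wt_like"


@dataclass(frozen=True)
class AccuracyReport:
    n_deleterious_predicted: int
    n_deleterious_confirmed: int
    deleterious_success_rate: float
    n_total: int
    n_correct: int
    overall_accuracy: float

    @property
    def deleterious_success_pct(self) -> float:
        return 100.0 * self.deleterious_success_rate

    @property
    def overall_accuracy_pct(self) -> float:
        return 100.0 * self.overall_accuracy

    def as_dict(self) -> dict:
        return {
            "n_deleterious_predicted": self.n_deleterious_predicted,
            "n_deleterious_confirmed": self.n_deleterious_confirmed,
            "deleterious_success_rate": self.deleterious_success_rate,
            "n_total": self.n_total,
            "n_correct": self.n_correct,
            "overall_accuracy": self.overall_accuracy,
        }


def load_paper_outcomes(path: str | Path | None = None) -> list[EvaluationRecord]:
    """The bundled 10-variant prediction/outcome table (or any TSV with
    columns label, predicted, outcome)."""
    if path is None:
        text = resources.files("gefscan.data").joinpath("experimental_outcomes.tsv").read_text()
    else:
        text = Path(path).read_text()
    records: list[EvaluationRecord] = []
    header: list[str] | None = None
    for ln in text.splitlines():
        if not ln.strip() or ln.startswith("#"):
            continue
        if header is None:
            header = ln.split("\t")
            continue
        rec = dict(zip(header, ln.split("\t")))
        records.append(EvaluationRecord(rec["label"], rec["predicted"], rec["outcome"]))
    return records


def compute_accuracy(records: list[EvaluationRecord]) -> AccuracyReport:
    """Exact integer bookkeeping over prediction/outcome pairs."""
    if not records:
        raise ValueError("no evaluation records")
    n_del = sum(1 for r in records if r.predicted == "deleterious")
    n_del_ok = sum(1 for r in records if r.predicted == "deleterious" and r.match)
    n_ok = sum(1 for r in records if r.match)
    return AccuracyReport(
        n_deleterious_predicted=n_del,
        n_deleterious_confirmed=n_del_ok,
        deleterious_success_rate=(n_del_ok / n_del) if n_del else 0.0,
        n_total=len(records),
        n_correct=n_ok,
        overall_accuracy=n_ok / len(records),
    )
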