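"""Trial-summary data model and corpus CSV input/output.

A *corpus* is a collection of meta-analyses ("reviews"), each holding the
two-arm summary statistics (n, mean, SD per arm) of at least three
randomized trials reporting the same continuous outcome.  The CSV schema is
flat, one row per trial::

    review_id,study_id,n_t,mean_t,sd_t,n_c,mean_c,sd_c

with a required header, UTF-8 encoding and '.' decimal separator — the same
per-trial quantities a forest plot of continuous outcomes displays.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

logger = logging.getLogger(__name__)

CSV_COLUMNS = ("review_id", "study_id", "n_t", "mean_t", "sd_t", "n_c", "mean_c", "sd_c")

#: Minimum number of trials for a meta-analysis to enter the corpus.  Three
#: is the smallest size for which the leave-one-out agreement statistic is
#: defined (each holdout must leave a poolable pair behind).
MIN_TRIALS = 3


class CorpusError(ValueError):
    """Base class for corpus validation failures."""


class SchemaError(CorpusError):
    """The CSV header does not match the documented column schema."""


class RowError(CorpusError):
    """A data row is malformed or violates a trial-level invariant."""


class GroupError(CorpusError):
    """A review violates a group-level invariant (e.g. fewer than 3 trials)."""


@dataclass(frozen=True)
class TrialSummary:
    """Two-arm summary statistics of a single randomized trial.

    ``n_t, mean_t, sd_t`` describe the treatment arm and ``n_c, mean_c,
    sd_c`` the control arm, all in the outcome's natural units.  Each arm
    needs at least two participants (so the sample SD exists) and a strictly
    positive SD (so the standardized effect is defined).
    """

    review_id: str
    study_id: str
    n_t: int
    mean_t: float
    sd_t: float
    n_c: int
    mean_c: float
    sd_c: float

    def validate(self) -> None:
        if self.n_t < 2 or self.n_c < 2:
            raise RowError(
                f"{self.review_id}/{self.study_id}: each arm needs n >= 2 "
                f"(got n_t={self.n_t}, n_c={self.n_c})"
            )
        if not (self.sd_t > 0 and self.sd_c > 0):
            raise RowError(
                f"{self.review_id}/{self.study_id}: arm SDs must be > 0 "
                f"(got sd_t={self.sd_t}, sd_c={self.sd_c})"
            )
        for name in ("mean_t", "sd_t", "mean_c", "sd_c"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise RowError(f"{self.review_id}/{self.study_id}: {name} is not finite")


@dataclass(frozen=True)
class MetaAnalysisGroup:
    """All trials contributing to one review's continuous outcome.

    Trial order is preserved from the input file and fixes the iteration
    order of the leave-one-out procedure.
    """

    review_id: str
    trials: tuple[TrialSummary, ...]

    def validate(self) -> None:
        if len(self.trials) < MIN_TRIALS:
            raise GroupError(
                f"review {self.review_id!r} has {len(self.trials)} trials; "
                f"at least {MIN_TRIALS} required"
            )
        for t in self.trials:
            if t.review_id != self.review_id:
                raise GroupError(
                    f"trial {t.study_id!r} carries review_id {t.review_id!r} "
                    f"inside group {self.review_id!r}"
                )
            t.validate()
        ids = [t.study_id for t in self.trials]
        if len(set(ids)) != len(ids):
            raise GroupError(f"review {self.review_id!r} has duplicate study_ids")

    def __len__(self) -> int:
        return len(self.trials)


@dataclass(frozen=True)
class Corpus:
    """A keyed collection of meta-analysis groups."""

    groups: dict[str, MetaAnalysisGroup] = field(default_factory=dict)

    def validate(self) -> None:
        for rid, g in self.groups.items():
            if g.review_id != rid:
                raise CorpusError(f"group keyed {rid!r} carries review_id {g.review_id!r}")
            g.validate()

    def __len__(self) -> int:
        return len(self.groups)

    def __iter__(self) -> Iterator[MetaAnalysisGroup]:
        return iter(self.groups.values())

    @property
    def n_trials(self) -> int:
        return sum(len(g) for g in self.groups.values())

    @classmethod
    def from_groups(cls, groups: Iterable[MetaAnalysisGroup]) -> "Corpus":
        d: dict[str, MetaAnalysisGroup] = {}
        for g in groups:
            if g.review_id in d:
                raise CorpusError(f"duplicate review_id {g.review_id!r}")
            d[g.review_id] = g
        return cls(groups=d)


def _parse_row(raw: dict[str, str], line_no: int) -> TrialSummary:
    try:
        return TrialSummary(
            review_id=raw["review_id"],
            study_id=raw["study_id"],
            n_t=int(raw["n_t"]),
            mean_t=float(raw["mean_t"]),
            sd_t=float(raw["sd_t"]),
            n_c=int(raw["n_c"]),
            mean_c=float(raw["mean_c"]),
            sd_c=float(raw["sd_c"]),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise RowError(f"line {line_no}: cannot parse row: {exc}") from exc


def read_corpus(path: str | Path, strict: bool = True) -> Corpus:
    """Read and validate a corpus CSV.

    In strict mode (default) any malformed row, invalid trial, or review
    with fewer than three valid trials raises.  In lenient mode invalid
    rows are dropped with a logged count, and reviews left with fewer than
    three valid trials are dropped as well.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, header row required")
        if tuple(reader.fieldnames) != CSV_COLUMNS:
            raise SchemaError(
                f"{path}: header {reader.fieldnames} does not match "
                f"expected schema {list(CSV_COLUMNS)}"
            )
        by_review: dict[str, list[TrialSummary]] = {}
        n_bad_rows = 0
        for line_no, raw in enumerate(reader, start=2):
            try:
                trial = _parse_row(raw, line_no)
                trial.validate()
            except RowError as exc:
                if strict:
                    raise
                n_bad_rows += 1
                logger.warning("dropping invalid row: %s", exc)
                continue
            by_review.setdefault(trial.review_id, []).append(trial)

    groups: list[MetaAnalysisGroup] = []
    n_small = 0
    for rid, trials in by_review.items():
        g = MetaAnalysisGroup(review_id=rid, trials=tuple(trials))
        if len(g) < MIN_TRIALS:
            if strict:
                g.validate()  # raises GroupError with a precise message
            n_small += 1
            logger.warning(
                "dropping review %r: only %d valid trials (< %d)", rid, len(g), MIN_TRIALS
            )
            continue
        g.validate()
        groups.append(g)
    if n_bad_rows or n_small:
        logger.info(
            "lenient read of %s: dropped %d rows and %d undersized reviews",
            path, n_bad_rows, n_small,
        )
    return Corpus.from_groups(groups)


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus to CSV.  Floats use ``repr`` so the round trip is exact."""
    corpus.validate()
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for group in corpus:
            for t in group.trials:
                writer.writerow(
                    [t.review_id, t.study_id, t.n_t, repr(t.mean_t), repr(t.sd_t),
                     t.n_c, repr(t.mean_c), repr(t.sd_c)]
                )
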