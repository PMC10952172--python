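"""Read, validate, and summarize long-format survey data.

The expected input is a long CSV with one row per
(participant, identity, behaviour) triple::

    participant_id,identity,behaviour
    P1,student,studying
    P1,student,drinking
    P1,gamer,

An empty behaviour field records an identity with no behaviours attached.
Labels are whitespace-normalized and case-folded on ingestion; the free-text
coding that produces these labels is assumed to have happened upstream.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("participant_id", "identity", "behaviour")

#: Survey capped the number of identities a participant could list.
MAX_IDENTITIES = 10


class SurveyFormatError(ValueError):
    """Raised when an input file does not follow the long-CSV dialect."""


@dataclass
class Participant:
    participant_id: str
    identities: list[str]
    behaviours_by_identity: dict[str, list[str]]

    def __post_init__(self) -> None:
        if len(set(self.identities)) != len(self.identities):
            raise ValueError(f"duplicate identities for {self.participant_id}")
        extra = set(self.behaviours_by_identity) - set(self.identities)
        if extra:
            raise ValueError(
                f"behaviours attached to unlisted identities for "
                f"{self.participant_id}: {sorted(extra)}"
            )
        # every identity has an entry, possibly empty
        for ident in self.identities:
            self.behaviours_by_identity.setdefault(ident, [])


@dataclass
class SurveyDataset:
    """A validated collection of participants with their identity/behaviour lists."""

    participants: list[Participant] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.participant_id for p in self.participants]
        if len(set(ids)) != len(ids):
            raise ValueError("participant_ids are not unique")

    def __len__(self) -> int:
        return len(self.participants)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SurveyDataset):
            return NotImplemented
        return self.to_records() == other.to_records()

    def to_records(self) -> list[tuple[str, str, str]]:
        """Flatten to sorted (participant, identity, behaviour) triples.

        Identity-only entries appear with an empty behaviour string.
        """
        rows: list[tuple[str, str, str]] = []
        for p in self.participants:
            for ident in p.identities:
                behs = p.behaviours_by_identity.get(ident, [])
                if behs:
                    rows.extend((p.participant_id, ident, b) for b in behs)
                else:
                    rows.append((p.participant_id, ident, ""))
        return sorted(rows)

    @property
    def identity_vocabulary(self) -> list[str]:
        return sorted({i for p in self.participants for i in p.identities})

    @property
    def behaviour_vocabulary(self) -> list[str]:
        return sorted(
            {
                b
                for p in self.participants
                for bs in p.behaviours_by_identity.values()
                for b in bs
            }
        )

    def identity_counts(self) -> dict[str, int]:
        """Number of participants reporting each identity."""
        c: Counter[str] = Counter()
        for p in self.participants:
            c.update(set(p.identities))
        return dict(c)

    def behaviour_counts(self) -> dict[str, int]:
        """Number of (participant, identity) entries listing each behaviour."""
        c: Counter[str] = Counter()
        for p in self.participants:
            for behs in p.behaviours_by_identity.values():
                c.update(set(behs))
        return dict(c)


@dataclass
class SummaryTuple:
    mean: float
    sd: float
    mode: int
    min: int
    max: int

    def as_dict(self) -> dict[str, float]:
        return {
            "mean": self.mean,
            "sd": self.sd,
            "mode": self.mode,
            "min": self.min,
            "max": self.max,
        }


@dataclass
class DatasetSummary:
    n_participants: int
    identities_per_participant: SummaryTuple
    behaviours_per_identity: SummaryTuple
    behaviours_per_person: SummaryTuple
    label_frequency: dict[str, int]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_participants": self.n_participants,
            "identities_per_participant": self.identities_per_participant.as_dict(),
            "behaviours_per_identity": self.behaviours_per_identity.as_dict(),
            "behaviours_per_person": self.behaviours_per_person.as_dict(),
            "label_frequency": self.label_frequency,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def _norm_label(raw: object) -> str:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return ""
    return " ".join(str(raw).split()).casefold()


def read_survey(path: str | Path, format: str = "long_csv") -> SurveyDataset:
    """Read and validate a long-format survey CSV.

    Duplicate (participant, identity, behaviour) rows are collapsed; rows with
    an empty identity raise :class:`SurveyFormatError`. A participant listing
    more than the survey cap of 10 identities is kept with a warning.
    """
    if format != "long_csv":
        raise SurveyFormatError(f"unknown format: {format}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SurveyFormatError(f"missing required columns: {missing}")
    return dataset_from_rows(
        (r.participant_id, r.identity, r.behaviour) for r in df.itertuples()
    )


def dataset_from_rows(rows) -> SurveyDataset:
    """Build a SurveyDataset from (participant, identity, behaviour) triples."""
    participants: dict[str, Participant] = {}
    seen: set[tuple[str, str, str]] = set()
    for pid_raw, ident_raw, beh_raw in rows:
        pid = _norm_label(pid_raw)
        ident = _norm_label(ident_raw)
        beh = _norm_label(beh_raw)
        if not pid:
            raise SurveyFormatError("empty participant_id")
        if not ident:
            raise SurveyFormatError(f"empty identity for participant {pid!r}")
        key = (pid, ident, beh)
        if key in seen:
            continue
        seen.add(key)
        p = participants.setdefault(pid, Participant(pid, [], {}))
        if ident not in p.behaviours_by_identity:
            p.identities.append(ident)
            p.behaviours_by_identity[ident] = []
        if beh and beh not in p.behaviours_by_identity[ident]:
            p.behaviours_by_identity[ident].append(beh)
    for p in participants.values():
        if len(p.identities) > MAX_IDENTITIES:
            warnings.warn(
                f"participant {p.participant_id!r} lists {len(p.identities)} "
                f"identities (survey cap is {MAX_IDENTITIES}); kept",
                stacklevel=2,
            )
    return SurveyDataset(list(participants.values()))


def write_survey(dataset: SurveyDataset, path: str | Path) -> None:
    """Write the long-CSV dialect read by :func:`read_survey`."""
    df = pd.DataFrame(dataset.to_records(), columns=list(REQUIRED_COLUMNS))
    df.to_csv(path, index=False)


def _summary_tuple(values: list[int]) -> SummaryTuple:
    arr = np.asarray(values, dtype=float)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    counts = Counter(values)
    top = max(counts.values())
    mode = min(v for v, c in counts.items() if c == top)  # smallest among ties
    return SummaryTuple(float(arr.mean()), sd, int(mode), int(arr.min()), int(arr.max()))


def summarize(dataset: SurveyDataset) -> DatasetSummary:
    """Descriptive statistics: identities per participant, behaviours per
    identity and per person, and label occurrence counts.

    SDs are sample SDs (n-1); modes break ties to the smallest value.
    """
    if not dataset.participants:
        raise ValueError("empty dataset")
    idents_pp = [len(p.identities) for p in dataset.participants]
    behs_pi = [
        len(bs) for p in dataset.participants for bs in p.behaviours_by_identity.values()
    ]
    behs_pp = [
        sum(len(bs) for bs in p.behaviours_by_identity.values())
        for p in dataset.participants
    ]
    freq: Counter[str] = Counter(dataset.identity_counts())
    freq.update(dataset.behaviour_counts())
    return DatasetSummary(
        n_participants=len(dataset),
        identities_per_participant=_summary_tuple(idents_pp),
        behaviours_per_identity=_summary_tuple(behs_pi or [0]),
        behaviours_per_person=_summary_tuple(behs_pp),
        label_frequency=dict(freq),
    )


def filter_items(counts: dict[str, int], min_count: int = 3) -> set[str]:
    """Labels observed strictly more than ``min_count`` times.

    The default of 3 keeps nodes observed more than three times (count >= 4),
    the filter applied before all structural analyses.
    """
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    return {label for label, c in counts.items() if c > min_count}
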