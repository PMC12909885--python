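"""Dataset bookkeeping: labeled image records and the manifest ledger.

The manifest is the single source of truth for what exists on disk, which
split each image belongs to and where derived images came from.  Counts are
always recomputed from the records — nothing is cached — so the ledger can
never drift from its own rows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

SPLITS = ("unassigned", "test", "train", "val")
PROVENANCES = ("original", "augmented", "gan", "filtered")

CLASS_NAMES = (
    "brazil_nut", "cashew", "chestnut", "peanut",
    "pecan_nut", "pistachio", "macadamia", "walnut",
)


@dataclass
class LabeledImage:
    id: str
    path: str
    class_label: str
    split: str = "unassigned"
    provenance: str = "original"
    source_id: str | None = None

    def __post_init__(self):
        if self.split not in SPLITS:
            raise ValueError(f"unknown split {self.split!r}")
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")


@dataclass
class DatasetManifest:
    class_names: tuple[str, ...]
    records: list[LabeledImage] = field(default_factory=list)

    def add(self, record: LabeledImage) -> None:
        self.records.append(record)

    def extend(self, records) -> None:
        self.records.extend(records)

    def __len__(self) -> int:
        return len(self.records)

    def check_unique_ids(self) -> None:
        seen = set()
        for r in self.records:
            if r.id in seen:
                raise ValueError(f"duplicate id {r.id!r}")
            seen.add(r.id)

    def by_id(self) -> dict[str, LabeledImage]:
        return {r.id: r for r in self.records}

    def select(self, split=None, provenance=None, class_label=None):
        out = []
        for r in self.records:
            if split is not None and r.split != split:
                continue
            if provenance is not None and r.provenance != provenance:
                continue
            if class_label is not None and r.class_label != class_label:
                continue
            out.append(r)
        return out

    def counts(self) -> pd.DataFrame:
        """(class x split x provenance) count table, recomputed from records."""
        if not self.records:
            return pd.DataFrame(columns=["class_label", "split", "provenance", "n"])
        df = self.to_frame()
        return (df.groupby(["class_label", "split", "provenance"])
                  .size().rename("n").reset_index())

    def count(self, **kw) -> int:
        return len(self.select(**kw))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"id": r.id, "path": r.path, "class": r.class_label,
              "split": r.split, "provenance": r.provenance,
              "source_id": r.source_id if r.source_id is not None else ""}
             for r in self.records],
            columns=["id", "path", "class", "split", "provenance", "source_id"],
        ).rename(columns={"class": "class_label"})

    def copy(self) -> "DatasetManifest":
        return DatasetManifest(self.class_names, [replace(r) for r in self.records])

    # ---------------------------------------------------------------- I/O
    def save(self, stem: Path | str) -> None:
        """Write ``<stem>.csv`` and a JSON mirror ``<stem>.json``."""
        stem = Path(stem)
        df = self.to_frame().rename(columns={"class_label": "class"})
        df = df[["path", "class", "split", "provenance", "source_id", "id"]]
        df.to_csv(stem.with_suffix(".csv"), index=False)
        payload = {
            "class_names": list(self.class_names),
            "records": df.to_dict(orient="records"),
        }
        stem.with_suffix(".json").write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, stem: Path | str) -> "DatasetManifest":
        stem = Path(stem)
        payload = json.loads(stem.with_suffix(".json").read_text())
        records = [
            LabeledImage(
                id=row["id"], path=row["path"], class_label=row["class"],
                split=row["split"], provenance=row["provenance"],
                source_id=row["source_id"] or None)
            for row in payload["records"]
        ]
        return cls(tuple(payload["class_names"]), records)
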