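"""Activity-table preparation: loading, cleaning, filtering, augmentation, holdout.

The rules implemented here mirror a common recipe for building binary
bioactivity models from large public extracts (ChEMBL/PubChem-style
tables with a gene symbol, an entry ID, a SMILES and an A/N activity
flag):

* rows whose (target, SMILES) key carries *both* labels are removed
  entirely — conflicting evidence is discarded, not majority-voted;
* duplicate rows are collapsed to a single entry, by default on the
  (target, canonical SMILES, activity) key;
* targets are kept only when they have at least ``min_actives`` actives
  and ``min_nonactives`` non-actives;
* targets with few known non-actives are augmented with randomly drawn
  "assumed non-active" compounds — molecules never reported active for
  that target — until non-actives reach ``nonactive_ratio`` times the
  actives.  Augmented records are flagged so that downstream conformal
  calibration can exclude them;
* an external-validation split moves records matching a given compound
  ID list out of the training pool.
"""

from __future__ import annotations

import csv
import gzip
import json
import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from rdkit import Chem

logger = logging.getLogger(__name__)

__all__ = [
    "ActivityRecord",
    "DatasetRecord",
    "TargetDataset",
    "PrepConfig",
    "ExclusionReport",
    "load_activity_records",
    "iter_activity_records",
    "remove_conflicts",
    "deduplicate",
    "select_targets",
    "add_assumed_nonactives",
    "withhold_external",
    "prepare_targets",
    "write_target_table",
    "write_exclusion_report",
    "write_provenance",
]

DEFAULT_COLUMNS = {
    "target": "target",
    "entry_id": "entry_id",
    "smiles": "smiles",
    "activity": "activity",
}


@dataclass(frozen=True)
class ActivityRecord:
    """One row of an activity table."""

    target: str
    entry_id: str
    smiles: str
    activity: str  # "A" or "N"


@dataclass(frozen=True)
class DatasetRecord:
    smiles: str
    activity: str
    assumed_nonactive: bool
    entry_id: str


@dataclass
class TargetDataset:
    """Cleaned, possibly augmented, records for a single target."""

    target: str
    records: list[DatasetRecord]

    @property
    def n_actives(self) -> int:
        return sum(1 for r in self.records if r.activity == "A")

    @property
    def n_nonactives(self) -> int:
        return sum(1 for r in self.records if r.activity == "N")

    @property
    def n_known_nonactives(self) -> int:
        return sum(
            1 for r in self.records if r.activity == "N" and not r.assumed_nonactive
        )

    @property
    def n_assumed(self) -> int:
        return sum(1 for r in self.records if r.assumed_nonactive)

    def validate(self) -> None:
        seen: dict[str, str] = {}
        pairs = set()
        for r in self.records:
            if r.assumed_nonactive and r.activity != "N":
                raise ValueError("assumed non-active record labelled A")
            if (r.smiles, r.activity) in pairs:
                raise ValueError(f"duplicate (smiles, activity): {r.smiles}")
            pairs.add((r.smiles, r.activity))
            if r.smiles in seen and seen[r.smiles] != r.activity:
                raise ValueError(f"conflicting labels for {r.smiles}")
            seen[r.smiles] = r.activity


@dataclass(frozen=True)
class PrepConfig:
    min_actives: int = 100
    min_nonactives: int = 100
    augmentation_threshold: int = 10_000
    nonactive_ratio: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if min(self.min_actives, self.min_nonactives, self.augmentation_threshold) <= 0:
            raise ValueError("thresholds must be positive")
        if self.nonactive_ratio <= 0:
            raise ValueError("nonactive_ratio must be positive")


@dataclass
class ExclusionReport:
    rows: list[tuple[str, int, int, str]] = field(default_factory=list)  # target, n_A, n_N, reason


@lru_cache(maxsize=1_000_000)
def canonical_smiles(smiles: str) -> str:
    """RDKit-canonical form of a SMILES, or the raw string if unparseable."""
    mol = Chem.MolFromSmiles(smiles)
    return smiles if mol is None else Chem.MolToSmiles(mol)


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def iter_activity_records(
    path,
    column_map: dict | None = None,
    delimiter: str = "\t",
) -> Iterator[ActivityRecord]:
    """Stream records from a delimited text file (gzip-transparent).

    Rows with an activity flag other than A/N, or with empty mapped
    fields, are skipped; the skip count is logged once at the end.
    Missing mapped columns are fatal.
    """
    cols = {**DEFAULT_COLUMNS, **(column_map or {})}
    skipped = 0
    total = 0
    with _open_text(path) as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        missing = [c for c in cols.values() if c not in header]
        if missing:
            raise ValueError(f"missing required column(s) {missing} in {path}")
        for row in reader:
            total += 1
            vals = {k: (row.get(col) or "").strip() for k, col in cols.items()}
            if vals["activity"] not in ("A", "N") or not all(vals.values()):
                skipped += 1
                continue
            yield ActivityRecord(
                target=vals["target"],
                entry_id=vals["entry_id"],
                smiles=vals["smiles"],
                activity=vals["activity"],
            )
    if skipped:
        logger.warning("skipped %d of %d rows with unmapped/malformed values", skipped, total)
    if total == 0:
        logger.warning("activity table %s is empty", path)


def load_activity_records(path, column_map: dict | None = None, delimiter: str = "\t") -> list[ActivityRecord]:
    return list(iter_activity_records(path, column_map, delimiter))


def _key_smiles(record: ActivityRecord, canonicalize: bool) -> str:
    return canonical_smiles(record.smiles) if canonicalize else record.smiles


def remove_conflicts(
    records: Sequence[ActivityRecord], canonicalize: bool = True
) -> list[ActivityRecord]:
    """Drop *all* rows of any (target, SMILES) key that carries both labels."""
    labels: dict[tuple[str, str], set[str]] = {}
    for r in records:
        labels.setdefault((r.target, _key_smiles(r, canonicalize)), set()).add(r.activity)
    kept = [
        r for r in records
        if len(labels[(r.target, _key_smiles(r, canonicalize))]) == 1
    ]
    dropped = len(records) - len(kept)
    if dropped:
        logger.info("removed %d rows with conflicting activity labels", dropped)
    return kept


def deduplicate(
    records: Sequence[ActivityRecord],
    canonicalize: bool = True,
    include_entry_id: bool = False,
) -> list[ActivityRecord]:
    """Collapse duplicate rows to a single entry.

    The default key is (target, SMILES, activity) — SMILES-level
    deduplication, keeping the first-seen entry ID.  With
    ``include_entry_id`` the entry ID joins the key, the literal
    "identical extracted row" reading.
    """
    seen = set()
    out = []
    for r in records:
        key = (r.target, _key_smiles(r, canonicalize), r.activity) + (
            (r.entry_id,) if include_entry_id else ()
        )
        if key in seen:
            continue
        seen.add(key)
        out.append(r)
    return out


def select_targets(
    records: Sequence[ActivityRecord], config: PrepConfig = PrepConfig()
) -> tuple[dict[str, TargetDataset], ExclusionReport]:
    """Keep targets with at least ``min_actives`` A and ``min_nonactives`` N rows."""
    by_target: dict[str, list[ActivityRecord]] = {}
    for r in records:
        by_target.setdefault(r.target, []).append(r)
    datasets: dict[str, TargetDataset] = {}
    report = ExclusionReport()
    for target in sorted(by_target):
        recs = by_target[target]
        n_a = sum(1 for r in recs if r.activity == "A")
        n_n = len(recs) - n_a
        if n_a >= config.min_actives and n_n >= config.min_nonactives:
            datasets[target] = TargetDataset(
                target=target,
                records=[
                    DatasetRecord(r.smiles, r.activity, False, r.entry_id)
                    for r in recs
                ],
            )
        else:
            reasons = []
            if n_a < config.min_actives:
                reasons.append(f"actives {n_a} < {config.min_actives}")
            if n_n < config.min_nonactives:
                reasons.append(f"non-actives {n_n} < {config.min_nonactives}")
            report.rows.append((target, n_a, n_n, "; ".join(reasons)))
    return datasets, report


def add_assumed_nonactives(
    ds: TargetDataset,
    pool: Sequence[ActivityRecord],
    config: PrepConfig = PrepConfig(),
    rng: np.random.Generator | None = None,
) -> TargetDataset:
    """Augment a target with assumed non-actives to ``nonactive_ratio`` x actives.

    Eligible pool compounds are those not reported active for this
    target and not already in the dataset; ``max(0, ceil(ratio * n_A) -
    n_N)`` distinct SMILES are drawn uniformly without replacement.  If
    the pool is too small every eligible compound is added with a
    warning.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n_a, n_n = ds.n_actives, ds.n_nonactives
    n_needed = max(0, math.ceil(config.nonactive_ratio * n_a) - n_n)
    if n_needed == 0:
        return ds
    present = {canonical_smiles(r.smiles) for r in ds.records}
    active_for_target = {
        canonical_smiles(r.smiles)
        for r in pool
        if r.target == ds.target and r.activity == "A"
    }
    eligible: dict[str, ActivityRecord] = {}
    for r in pool:
        key = canonical_smiles(r.smiles)
        if key in present or key in active_for_target or key in eligible:
            continue
        eligible[key] = r
    keys = sorted(eligible)
    if len(keys) < n_needed:
        logger.warning(
            "pool has only %d eligible compounds for %s (wanted %d); adding all",
            len(keys), ds.target, n_needed,
        )
        chosen = keys
    else:
        chosen = [keys[i] for i in rng.choice(len(keys), size=n_needed, replace=False)]
    new_records = ds.records + [
        DatasetRecord(eligible[k].smiles, "N", True, eligible[k].entry_id)
        for k in sorted(chosen)
    ]
    return TargetDataset(target=ds.target, records=new_records)


def withhold_external(
    records: Sequence[ActivityRecord],
    compound_ids: Iterable[str],
    key: str = "entry_id",
) -> tuple[list[ActivityRecord], list[ActivityRecord]]:
    """Exact partition into (train, external) by entry ID or SMILES membership."""
    ids = set(compound_ids)
    if not ids:
        return list(records), []
    if key not in ("entry_id", "smiles"):
        raise ValueError("key must be 'entry_id' or 'smiles'")
    train, external = [], []
    matched = set()
    for r in records:
        value = r.entry_id if key == "entry_id" else r.smiles
        if value in ids:
            external.append(r)
            matched.add(value)
        else:
            train.append(r)
    unmatched = ids - matched
    if unmatched:
        logger.warning("%d withheld ids matched no record", len(unmatched))
    return train, external


def prepare_targets(
    records: Sequence[ActivityRecord],
    config: PrepConfig = PrepConfig(),
    pool: Sequence[ActivityRecord] | None = None,
    canonicalize: bool = True,
) -> tuple[dict[str, TargetDataset], ExclusionReport, dict]:
    """Full cleaning pipeline: conflicts -> dedup -> target filter -> augmentation.

    Targets whose known non-active count is below
    ``config.augmentation_threshold`` are augmented from ``pool``
    (default: the cleaned table itself).  Returns the per-target
    datasets, the exclusion report and a provenance dict of row counts
    at each stage.
    """
    provenance: dict = {"n_input": len(records), "seed": config.seed}
    cleaned = remove_conflicts(records, canonicalize=canonicalize)
    provenance["n_after_conflict_removal"] = len(cleaned)
    cleaned = deduplicate(cleaned, canonicalize=canonicalize)
    provenance["n_after_dedup"] = len(cleaned)
    datasets, report = select_targets(cleaned, config)
    provenance["n_targets_selected"] = len(datasets)
    provenance["n_targets_excluded"] = len(report.rows)
    pool = cleaned if pool is None else pool
    augmented: dict[str, TargetDataset] = {}
    for i, (target, ds) in enumerate(sorted(datasets.items())):
        if ds.n_known_nonactives < config.augmentation_threshold:
            rng = np.random.default_rng([config.seed, i])
            ds = add_assumed_nonactives(ds, pool, config, rng)
        augmented[target] = ds
    provenance["per_target"] = {
        t: {
            "n_actives": d.n_actives,
            "n_known_nonactives": d.n_known_nonactives,
            "n_assumed_nonactives": d.n_assumed,
        }
        for t, d in augmented.items()
    }
    return augmented, report, provenance


def write_target_table(ds: TargetDataset, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["target", "entry_id", "smiles", "activity", "assumed_nonactive"])
        for r in ds.records:
            w.writerow([ds.target, r.entry_id, r.smiles, r.activity, int(r.assumed_nonactive)])


def write_exclusion_report(report: ExclusionReport, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["target", "n_actives", "n_nonactives", "reason"])
        for row in report.rows:
            w.writerow(row)


def write_provenance(provenance: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
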