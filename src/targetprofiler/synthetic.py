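"""Synthetic multi-target activity tables with a known structure-activity signal.

Molecules are grown from a small grammar: an alkyl chain of random
length, an optional phenyl substituent, and random decorations from a
small alphabet.  Each simulated target is associated with a *motif* (a
chemically valid functional group such as a carboxylic acid or a nitro
group); molecules labelled active carry the motif, non-actives are
verified by substructure search not to.  Observed labels are then
flipped independently with probability ``label_noise`` so the Bayes
error of the classification task is known.  Because every molecule is an
independent draw from the same process, train/test exchangeability —
the only assumption conformal prediction needs — holds by construction.

The table generator can additionally inject exact duplicate rows and
conflicting (target, SMILES) label pairs, returning an exact ledger of
what was injected so the cleaning stages can be checked row-for-row.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .dataset import ActivityRecord

__all__ = [
    "MOTIFS",
    "SyntheticSpec",
    "SyntheticTable",
    "generate_molecules",
    "generate_train_test",
    "generate_activity_table",
]

# name -> (attachable SMILES fragment, SMARTS used to verify presence/absence)
MOTIFS: dict[str, tuple[str, str]] = {
    "carboxylic_acid": ("C(=O)O", "[CX3](=O)[OX2H1]"),
    "nitro": ("[N+](=O)[O-]", "[N+](=O)[O-]"),
    "nitrile": ("C#N", "C#N"),
    "trifluoromethyl": ("C(F)(F)F", "C(F)(F)F"),
    "sulfonamide": ("S(=O)(=O)N", "S(=O)(=O)[NX3]"),
    "chlorophenyl": ("c1ccc(Cl)cc1", "Clc1ccccc1"),
    "primary_amine": ("N", "[NX3;H2]"),
}

_DECORATIONS = ("C", "O", "F")


@dataclass
class SyntheticSpec:
    """Conditions for one synthetic study.

    Per target, ``n_active`` actives and ``n_nonactive`` non-actives are
    drawn; targets cycle through :data:`MOTIFS` unless ``motifs`` is
    given explicitly.
    """

    n_targets: int = 1
    n_active: int = 100
    n_nonactive: int = 100
    label_noise: float = 0.0
    duplicate_rate: float = 0.0
    conflict_rate: float = 0.0
    chain_length: tuple[int, int] = (3, 8)
    ring_probability: float = 0.4
    decoration_alphabet: tuple[str, ...] = _DECORATIONS
    motifs: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_targets < 1 or self.n_active < 1 or self.n_nonactive < 1:
            raise ValueError("counts must be positive")
        if not (0.0 <= self.label_noise < 0.5):
            raise ValueError("label_noise must be in [0, 0.5)")
        for r in (self.duplicate_rate, self.conflict_rate):
            if not (0.0 <= r < 1.0):
                raise ValueError("rates must be in [0, 1)")
        if self.motifs is not None:
            unknown = set(self.motifs) - set(MOTIFS)
            if unknown:
                raise ValueError(f"unknown motifs: {sorted(unknown)}")

    def motif_for(self, target_index: int) -> str:
        names = self.motifs if self.motifs is not None else tuple(MOTIFS)
        return names[target_index % len(names)]

    def target_name(self, target_index: int) -> str:
        return f"T{target_index + 1:03d}"


@dataclass
class SyntheticTable:
    """Generated records plus the bookkeeping needed for exact checks."""

    records: list[ActivityRecord]
    true_labels: dict[str, str] = field(default_factory=dict)  # entry_id -> pre-noise label
    duplicate_rows: list[ActivityRecord] = field(default_factory=list)
    conflict_keys: list[tuple[str, str]] = field(default_factory=list)
    n_conflict_rows: int = 0

    def truth_sidecar(self) -> dict:
        return {
            "true_labels": self.true_labels,
            "n_injected_duplicates": len(self.duplicate_rows),
            "conflict_keys": [list(k) for k in self.conflict_keys],
            "n_conflict_rows": self.n_conflict_rows,
        }


def _grow_smiles(rng: np.random.Generator, spec: SyntheticSpec, motif_fragment: str | None) -> str:
    lo, hi = spec.chain_length
    n = int(rng.integers(lo, hi + 1))
    branches: list[list[str]] = [[] for _ in range(n)]
    if rng.random() < spec.ring_probability:
        branches[int(rng.integers(n))].append("c1ccccc1")
    for _ in range(int(rng.integers(0, 3))):
        pos = int(rng.integers(n))
        if len(branches[pos]) < 2:
            branches[pos].append(str(rng.choice(spec.decoration_alphabet)))
    if motif_fragment is not None:
        open_positions = [i for i, b in enumerate(branches) if len(b) < 2]
        pos = int(rng.choice(open_positions)) if open_positions else int(rng.integers(n))
        branches[pos].append(motif_fragment)
    return "".join(
        "C" + "".join(f"({b})" for b in branch_list) for branch_list in branches
    )


def generate_molecules(
    spec: SyntheticSpec,
    target_index: int,
    rng: np.random.Generator | None = None,
    n_active: int | None = None,
    n_nonactive: int | None = None,
) -> list[tuple[str, str, str]]:
    """Draw ``(canonical smiles, observed label, true label)`` triples for one target.

    Pre-noise, actives contain the target's motif and non-actives do
    not; SMILES are canonical and unique within the returned set.
    """
    rng = rng if rng is not None else np.random.default_rng([spec.seed, target_index])
    motif_name = spec.motif_for(target_index)
    fragment, smarts = MOTIFS[motif_name]
    query = Chem.MolFromSmarts(smarts)
    n_act = spec.n_active if n_active is None else n_active
    n_non = spec.n_nonactive if n_nonactive is None else n_nonactive

    seen: set[str] = set()
    out: list[tuple[str, str, str]] = []
    for true_label, count in (("A", n_act), ("N", n_non)):
        made = 0
        for attempt in itertools.count():
            if made == count:
                break
            if attempt > 200 * count + 1000:
                raise RuntimeError(
                    f"molecule grammar failed to produce {count} distinct "
                    f"{true_label!r} molecules for motif {motif_name!r}"
                )
            smi = _grow_smiles(rng, spec, fragment if true_label == "A" else None)
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                continue
            has_motif = mol.HasSubstructMatch(query)
            if (true_label == "A") != has_motif:
                continue
            canonical = Chem.MolToSmiles(mol)
            if canonical in seen:
                continue
            seen.add(canonical)
            observed = true_label
            if spec.label_noise > 0 and rng.random() < spec.label_noise:
                observed = "N" if true_label == "A" else "A"
            out.append((canonical, observed, true_label))
            made += 1
    return out


def generate_train_test(
    spec: SyntheticSpec,
    target_index: int,
    n_test_active: int,
    n_test_nonactive: int,
    rng: np.random.Generator | None = None,
) -> tuple[list[tuple[str, str, str]], list[tuple[str, str, str]]]:
    """One joint draw of distinct molecules, randomly split into train and test.

    Molecules within one generator call are distinct (duplicates are
    redrawn), so two separate calls are each tilted away from the
    grammar's most probable molecules and are *not* exchangeable with
    each other.  Drawing the union once and splitting it at random makes
    train and test exchangeable by construction, which is the assumption
    conformal validity rests on.
    """
    rng = rng if rng is not None else np.random.default_rng([spec.seed, target_index, 55])
    triples = generate_molecules(
        spec, target_index, rng=rng,
        n_active=spec.n_active + n_test_active,
        n_nonactive=spec.n_nonactive + n_test_nonactive,
    )
    actives = [t for t in triples if t[2] == "A"]
    nonactives = [t for t in triples if t[2] == "N"]
    train: list[tuple[str, str, str]] = []
    test: list[tuple[str, str, str]] = []
    for group, n_test in ((actives, n_test_active), (nonactives, n_test_nonactive)):
        order = rng.permutation(len(group))
        test.extend(group[i] for i in order[:n_test])
        train.extend(group[i] for i in order[n_test:])
    return train, test


def generate_activity_table(spec: SyntheticSpec) -> SyntheticTable:
    """Concatenated per-target records, with ledgered duplicate/conflict injection.

    Duplicates are exact row copies; conflicts add one opposite-label row
    for an existing (target, SMILES) key.  Keys chosen for conflict
    injection are disjoint from duplicated rows, so downstream cleaning
    can be checked exactly: conflict removal drops ``n_conflict_rows``
    rows (two per conflicted key) and deduplication drops
    ``len(duplicate_rows)`` rows.
    """
    rng = np.random.default_rng([spec.seed, 982451653])
    table = SyntheticTable(records=[])
    counter = itertools.count(1)
    base_by_target: dict[str, list[ActivityRecord]] = {}

    for t in range(spec.n_targets):
        target = spec.target_name(t)
        mols = generate_molecules(spec, t)
        recs = []
        for smi, observed, true in mols:
            rec = ActivityRecord(
                target=target,
                entry_id=f"SYN{next(counter):07d}",
                smiles=smi,
                activity=observed,
            )
            table.true_labels[rec.entry_id] = true
            recs.append(rec)
        base_by_target[target] = recs
        table.records.extend(recs)

    n_base = len(table.records)
    # conflicts first, then duplicates on the remaining keys, keeping the
    # two kinds of injected artifact disjoint
    n_conflicts = int(round(spec.conflict_rate * n_base))
    conflict_idx = set()
    if n_conflicts:
        conflict_idx = set(
            rng.choice(n_base, size=n_conflicts, replace=False).tolist()
        )
        for i in sorted(conflict_idx):
            base = table.records[i]
            flipped = ActivityRecord(
                target=base.target,
                entry_id=f"SYN{next(counter):07d}",
                smiles=base.smiles,
                activity="N" if base.activity == "A" else "A",
            )
            table.records.append(flipped)
            table.conflict_keys.append((base.target, base.smiles))
        table.n_conflict_rows = 2 * n_conflicts

    n_duplicates = int(round(spec.duplicate_rate * n_base))
    if n_duplicates:
        eligible = np.array(sorted(set(range(n_base)) - conflict_idx))
        chosen = rng.choice(eligible, size=min(n_duplicates, len(eligible)), replace=False)
        for i in sorted(chosen.tolist()):
            base = table.records[i]
            table.duplicate_rows.append(
                ActivityRecord(base.target, base.entry_id, base.smiles, base.activity)
            )
        table.records.extend(table.duplicate_rows)

    perm = rng.permutation(len(table.records))
    table.records = [table.records[i] for i in perm]
    return table
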