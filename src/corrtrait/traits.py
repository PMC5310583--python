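"""Binary trait tables: loading, coding, and alignment to trees.

A codebook maps each trait's state names onto {0, 1}, e.g.::

    {"iris": {"dark": 0, "bright": 1},
     "nest": {"non-cavity": 0, "cavity": 1}}

State tokens and species labels are canonicalised (case-folded, trimmed,
underscores treated as spaces) before matching, so ``"Bright "`` codes the
same as ``"bright"`` and ``Parus_major`` joins ``Parus major``.  The
reserved missing marker is ``"?"``; empty cells and NaN are also missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import treeio
from .models import encode_pair

__all__ = [
    "TraitTable",
    "PairedStates",
    "AlignmentReport",
    "load_trait_table",
    "pair_and_align",
    "canonical_label",
]

MISSING = "?"


def canonical_label(label: str) -> str:
    return " ".join(str(label).replace("_", " ").split()).casefold()


def _canonical_state(token) -> str:
    return str(token).strip().casefold()


@dataclass
class TraitTable:
    """Species x trait table of coded binary states (-1 = missing)."""

    data: pd.DataFrame  # index: species label (original); int8 columns
    codebook: dict[str, dict[str, int]]

    @property
    def traits(self) -> list[str]:
        return list(self.data.columns)

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    def counts(self) -> pd.DataFrame:
        """Per-trait counts of state 0, state 1 and missing."""
        rows = {}
        for t in self.traits:
            col = self.data[t]
            rows[t] = {
                "n0": int((col == 0).sum()),
                "n1": int((col == 1).sum()),
                "missing": int((col == -1).sum()),
            }
        return pd.DataFrame(rows).T

    def states(self, trait: str) -> dict[str, int]:
        """Non-missing species -> state mapping for one trait."""
        col = self.data[trait]
        return {sp: int(v) for sp, v in col.items() if v != -1}


@dataclass
class PairedStates:
    """Species -> combined 4-state index for an ordered trait pair."""

    states: dict[str, int]
    trait1: str
    trait2: str

    def __len__(self):
        return len(self.states)

    def __getitem__(self, sp):
        return self.states[sp]

    def items(self):
        return self.states.items()


@dataclass
class AlignmentReport:
    n_used: int = 0
    dropped_missing: list[str] = field(default_factory=list)
    dropped_not_on_tree: list[str] = field(default_factory=list)
    tips_without_data: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [("missing_trait", sp) for sp in self.dropped_missing]
        rows += [("not_on_tree", sp) for sp in self.dropped_not_on_tree]
        rows += [("tip_without_data", sp) for sp in self.tips_without_data]
        return pd.DataFrame(rows, columns=["reason", "species"])


def load_trait_table(
    path,
    codebook: dict[str, dict[str, int]],
    *,
    species_column: str = "species",
    sep: str | None = None,
) -> TraitTable:
    """Read a delimited trait file and code states per the codebook.

    Raises on duplicate species and on state tokens absent from the
    codebook (naming the offending row); returns the coded table.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    raw = pd.read_csv(path, sep=sep, dtype=str)
    if species_column not in raw.columns:
        raise ValueError(
            f"species column {species_column!r} not in header {list(raw.columns)}"
        )
    species = raw[species_column].astype(str).str.strip()
    dup = species[species.duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate species labels: {sorted(set(dup))}")

    coded = {}
    for trait, states in codebook.items():
        if trait not in raw.columns:
            raise ValueError(f"trait column {trait!r} missing from file")
        lookup = {_canonical_state(k): int(v) for k, v in states.items()}
        vals = np.full(len(raw), -1, dtype=np.int8)
        for i, tok in enumerate(raw[trait]):
            if pd.isna(tok):
                continue
            c = _canonical_state(tok)
            if c in ("", MISSING, "na", "nan"):
                continue
            if c not in lookup:
                raise ValueError(
                    f"row {i + 2}: state {tok!r} for trait {trait!r} "
                    f"not in codebook {sorted(states)}"
                )
            vals[i] = lookup[c]
        coded[trait] = vals
    df = pd.DataFrame(coded, index=pd.Index(species, name=species_column))
    return TraitTable(data=df, codebook={t: dict(s) for t, s in codebook.items()})


def pair_and_align(
    table: TraitTable,
    trait1: str,
    trait2: str,
    tree,
    *,
    min_species: int = 4,
):
    """Complete-case pairing of two traits with tree pruning.

    Species missing either trait, and species absent from the tree, are
    dropped (and reported); the tree is pruned to the usable set.  Returns
    ``(PairedStates, pruned_tree, AlignmentReport)``.
    """
    for t in (trait1, trait2):
        if t not in table.traits:
            raise KeyError(f"trait {t!r} not in table columns {table.traits}")
    report = AlignmentReport()
    tips = treeio.tip_labels(tree)
    tip_by_canon = {canonical_label(l): l for l in tips}

    usable: dict[str, int] = {}
    for sp in table.species:
        s1 = int(table.data.at[sp, trait1])
        s2 = int(table.data.at[sp, trait2])
        if s1 == -1 or s2 == -1:
            report.dropped_missing.append(sp)
            continue
        tip = tip_by_canon.get(canonical_label(sp))
        if tip is None:
            report.dropped_not_on_tree.append(sp)
            continue
        usable[tip] = encode_pair(s1, s2)

    if len(usable) < min_species:
        raise ValueError(
            f"only {len(usable)} species have both traits and are on the tree; "
            f"need at least {min_species} for a 4-state model"
        )
    report.n_used = len(usable)
    report.tips_without_data = sorted(tips - set(usable))
    pruned, _ = treeio.prune_to_taxa(tree, set(usable))
    paired = PairedStates(states=usable, trait1=trait1, trait2=trait2)
    return paired, pruned, report
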