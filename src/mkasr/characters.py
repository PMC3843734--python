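"""Discrete character matrices and the two coding schemes.

A trait is a named column with a declared ordered alphabet of state names
(declared, not inferred, so a state absent from a subsample keeps its
index).  Cells hold a single state, a polymorphic state set, or MISSING.

Two codings feed the reconstruction methods:

* ``multistate`` — the trait as one k-state character (indices 0..k-1 in
  alphabet order);
* ``binary`` — k derived presence/absence characters, one per state
  ("state s present?", alphabet {absent, present} = {0, 1}).

Polymorphic cells become ambiguity sets in the multistate coding and score
"present" in every member's derived binary character.  MISSING is complete
ambiguity in every method.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

#: cell sentinel for missing data ("?" / blank in files)
MISSING = None

Cell = "frozenset[int] | None"


@dataclass(frozen=True)
class CodedCharacter:
    """One coded character: per-taxon allowed-state sets over a k-state alphabet."""

    name: str
    state_names: tuple[str, ...]
    states: dict  # taxon -> frozenset[int] | None (MISSING)

    @property
    def k(self) -> int:
        return len(self.state_names)

    @property
    def taxa(self) -> frozenset[str]:
        return frozenset(self.states)

    def allowed(self, taxon: str) -> frozenset[int]:
        """Allowed state indices for a taxon (full alphabet when MISSING)."""
        s = self.states[taxon]
        return frozenset(range(self.k)) if s is MISSING else s

    def restrict_to(self, taxa: Iterable[str]) -> "CodedCharacter":
        taxa = set(taxa)
        return CodedCharacter(
            self.name, self.state_names,
            {t: s for t, s in self.states.items() if t in taxa},
        )


class CharacterMatrix:
    """Taxa x traits matrix of discrete states with declared alphabets.

    ``alphabets`` maps trait name -> ordered state names; ``data`` maps
    ``(taxon, trait)`` to a frozenset of state indices or MISSING.
    """

    def __init__(
        self,
        taxa: Sequence[str],
        alphabets: Mapping[str, Sequence[str]],
        data: Mapping[tuple, Cell],
    ):
        if len(set(taxa)) != len(taxa):
            dup = sorted({t for t in taxa if list(taxa).count(t) > 1})
            raise ValueError(f"duplicate taxa: {dup}")
        self.taxa = list(taxa)
        self.alphabets = {t: tuple(a) for t, a in alphabets.items()}
        for trait, alpha in self.alphabets.items():
            if len(alpha) < 2:
                raise ValueError(f"trait {trait!r}: alphabet needs >= 2 states")
        self.data: dict[tuple, Cell] = {}
        for taxon in self.taxa:
            for trait, alpha in self.alphabets.items():
                cell = data.get((taxon, trait), MISSING)
                if cell is not MISSING:
                    cell = frozenset(cell)
                    bad = [i for i in cell if not 0 <= i < len(alpha)]
                    if bad:
                        raise ValueError(
                            f"taxon {taxon!r}, trait {trait!r}: "
                            f"state index {bad[0]} outside alphabet of size {len(alpha)}"
                        )
                self.data[(taxon, trait)] = cell

    @property
    def traits(self) -> list[str]:
        return list(self.alphabets)

    def cell(self, taxon: str, trait: str) -> Cell:
        return self.data[(taxon, trait)]

    def restrict_to(self, taxa: Iterable[str]) -> "CharacterMatrix":
        keep = [t for t in self.taxa if t in set(taxa)]
        return CharacterMatrix(keep, self.alphabets, self.data)

    # -- coding schemes ------------------------------------------------------

    def encode_multistate(self, trait: str) -> CodedCharacter:
        """The trait as a single k-state character in declared alphabet order."""
        alpha = self._alphabet(trait)
        states = {t: self.data[(t, trait)] for t in self.taxa}
        return CodedCharacter(trait, alpha, states)

    def encode_binary(self, trait: str) -> list[CodedCharacter]:
        """One presence/absence character per state of the trait.

        For taxon x and state s: 1 when x's state set contains s, 0 when it
        does not, MISSING when the source cell is MISSING.  Non-polymorphic
        taxa therefore carry exactly one 1 across the k derived characters.
        """
        alpha = self._alphabet(trait)
        out = []
        for si, sname in enumerate(alpha):
            states: dict = {}
            for t in self.taxa:
                cell = self.data[(t, trait)]
                if cell is MISSING:
                    states[t] = MISSING
                else:
                    states[t] = frozenset([1 if si in cell else 0])
            out.append(
                CodedCharacter(f"{trait}:{sname}", ("absent", "present"), states)
            )
        return out

    def _alphabet(self, trait: str) -> tuple[str, ...]:
        try:
            return self.alphabets[trait]
        except KeyError:
            raise KeyError(f"unknown trait {trait!r}; have {self.traits}") from None

    # -- file I/O ------------------------------------------------------------

    @classmethod
    def from_csv(
        cls, path: str | Path, alphabets: Mapping[str, Sequence[str]] | None = None
    ) -> "CharacterMatrix":
        """Read a taxa x traits CSV.

        First column = taxon label; header row = trait names.  Cells are
        state names, ``?``/empty for MISSING, or ``{a|b}`` for polymorphism.
        Without declared ``alphabets`` the alphabet of each trait is the
        sorted set of observed state names (discouraged for subsampled data).
        """
        with open(path, newline="") as fh:
            rows = list(csv.reader(fh))
        if not rows:
            raise ValueError(f"{path}: empty file")
        traits = rows[0][1:]
        taxa, parsed = [], {}
        for row in rows[1:]:
            if not row:
                continue
            taxon = row[0]
            taxa.append(taxon)
            for trait, raw in zip(traits, row[1:]):
                parsed[(taxon, trait)] = _parse_cell(raw)
        if alphabets is None:
            alphabets = {}
            for trait in traits:
                seen: set[str] = set()
                for taxon in taxa:
                    cell = parsed[(taxon, trait)]
                    if cell is not MISSING:
                        seen |= cell
                alphabets[trait] = sorted(seen)
        data = {}
        for (taxon, trait), cell in parsed.items():
            if cell is MISSING:
                data[(taxon, trait)] = MISSING
            else:
                alpha = list(alphabets[trait])
                idxs = set()
                for name in cell:
                    if name not in alpha:
                        raise ValueError(
                            f"taxon {taxon!r}, trait {trait!r}: "
                            f"undeclared state {name!r}"
                        )
                    idxs.add(alpha.index(name))
                data[(taxon, trait)] = frozenset(idxs)
        return cls(taxa, alphabets, data)

    @classmethod
    def from_nexus(
        cls, path: str | Path, alphabets: Mapping[str, Sequence[str]] | None = None
    ) -> "CharacterMatrix":
        """Read a NEXUS CHARACTERS/DATA block (standard data with SYMBOLS).

        Column i becomes trait ``char_i`` unless a CHARLABELS/CHARSTATELABELS
        block names it.  Symbols map to state indices in SYMBOLS order;
        ``alphabets`` may override the state *names* per trait (the symbol
        order must match).  ``?`` is MISSING; ``{..}`` polymorphism is kept.
        """
        import dendropy

        dm = dendropy.StandardCharacterMatrix.get(path=str(path),
                                                  schema="nexus")
        n_chars = max(len(seq) for seq in dm.values())
        taxa = [t.label for t in dm.taxon_namespace]
        trait_names = [f"char_{i}" for i in range(n_chars)]
        observed: list[set] = [set() for _ in range(n_chars)]
        cells: dict = {}
        for taxon in dm.taxon_namespace:
            for i, st in enumerate(dm[taxon]):
                if st.symbol in ("?", "-") or not (st.member_states or
                                                   st.symbol):
                    cells[(taxon.label, i)] = MISSING
                else:
                    syms = frozenset(
                        m.symbol for m in (st.member_states or [st]))
                    cells[(taxon.label, i)] = syms
                    observed[i] |= syms
        if alphabets is None:
            alphabets = {
                trait_names[i]: sorted(observed[i]) for i in range(n_chars)
            }
        data: dict = {}
        for (taxon, i), cell in cells.items():
            trait = trait_names[i]
            if cell is MISSING:
                data[(taxon, trait)] = MISSING
            else:
                alpha = list(alphabets[trait])
                bad = [sym for sym in cell if sym not in alpha]
                if bad:
                    raise ValueError(
                        f"taxon {taxon!r}, trait {trait!r}: "
                        f"undeclared symbol {bad[0]!r}"
                    )
                data[(taxon, trait)] = frozenset(alpha.index(s) for s in cell)
        return cls(taxa, alphabets, data)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["taxon"] + self.traits)
            for taxon in self.taxa:
                row = [taxon]
                for trait in self.traits:
                    cell = self.data[(taxon, trait)]
                    alpha = self.alphabets[trait]
                    if cell is MISSING:
                        row.append("?")
                    elif len(cell) == 1:
                        row.append(alpha[next(iter(cell))])
                    else:
                        row.append("{" + "|".join(alpha[i] for i in sorted(cell)) + "}")
                w.writerow(row)


def _parse_cell(raw: str):
    raw = raw.strip()
    if raw in ("", "?", "-"):
        return MISSING
    if raw.startswith("{") and raw.endswith("}"):
        names = [p.strip() for p in raw[1:-1].replace(",", "|").split("|")]
        return frozenset(n for n in names if n)
    return frozenset([raw])


# ---------------------------------------------------------------------------


def validate_against_tree(matrix: CharacterMatrix, tree, prune: bool = False):
    """Check that matrix taxa and tree tips agree; optionally prune the tree.

    Matrix taxa absent from the tree are always an error.  With
    ``prune=False`` tree tips absent from the matrix are also an error;
    with ``prune=True`` those tips are dropped from a copy of the tree and
    the pruned labels returned.

    Returns ``(matrix, tree, pruned_labels)``.
    """
    tips = tree.tip_labels
    mtaxa = set(matrix.taxa)
    extra_in_matrix = sorted(mtaxa - tips)
    if extra_in_matrix:
        raise ValueError(f"matrix taxa absent from tree: {extra_in_matrix}")
    extra_in_tree = sorted(tips - mtaxa)
    if extra_in_tree and not prune:
        raise ValueError(
            f"tree tips absent from matrix: {extra_in_tree} (use prune=True)"
        )
    if extra_in_tree:
        pruned = tree.clone()
        pruned.dtree.retain_taxa_with_labels(sorted(mtaxa))
        pruned._arrays = None
        return matrix, type(tree)(pruned.dtree), extra_in_tree
    return matrix, tree, []
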