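"""Readers and writers for the formats the pipeline touches.

NEXUS character matrices (DATA/CHARACTERS + ASSUMPTIONS blocks), Newick trees,
delimited taxon-age tables, and simple gap coding of FASTA alignments.

The in-memory containers are deliberately explicit: a character matrix stores,
per (taxon, character) cell, a *set* of state symbols — a singleton for a fixed
observation, a larger set for a polymorphism, and the full declared state space
for missing ('?') or inapplicable ('-') data.  Missing and gap codings are
treated identically (the full state set), matching default parsimony scoring in
PAUP*/TNT.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from .tree import PhyloTree

__all__ = [
    "CharacterSpec",
    "CharacterMatrix",
    "AgeTable",
    "read_nexus",
    "write_nexus",
    "read_newick",
    "write_newick",
    "read_age_table",
    "interval_midpoint_age",
    "simple_gap_code",
    "read_fasta_alignment",
    "MatrixError",
]


class MatrixError(ValueError):
    pass


KINDS = ("unordered", "ordered", "irreversible")


@dataclass
class CharacterSpec:
    """Per-character treatment: state space, ordering, weight, step costs."""

    char_id: int
    kind: str = "unordered"
    state_space: tuple[str, ...] = ("0", "1")
    weight: float = 1.0
    cost: Optional[np.ndarray] = None  # required for kind == "irreversible"

    def __post_init__(self):
        if self.kind not in KINDS:
            raise MatrixError(f"unknown character kind {self.kind!r}")
        self.state_space = tuple(str(s) for s in self.state_space)
        if len(set(self.state_space)) != len(self.state_space):
            raise MatrixError("duplicate symbols in state space")
        if not np.isfinite(self.weight) or self.weight < 0:
            raise MatrixError("weight must be a finite nonnegative real")
        if self.kind == "irreversible" and self.cost is None:
            raise MatrixError("irreversible characters require a cost table")
        if self.cost is not None:
            self.cost = np.asarray(self.cost, dtype=float)
            k = len(self.state_space)
            if self.cost.shape != (k, k):
                raise MatrixError("cost table must be square on the state space")
            if np.any(np.diag(self.cost) != 0):
                raise MatrixError("cost table diagonal must be zero")
            if np.any(self.cost < 0):
                raise MatrixError("cost table entries must be nonnegative")

    @property
    def n_states(self) -> int:
        return len(self.state_space)

    def cost_matrix(self) -> np.ndarray:
        """Step costs between states (unordered: unit; ordered: rank distance)."""
        if self.cost is not None:
            return self.cost
        k = self.n_states
        if self.kind == "ordered":
            idx = np.arange(k, dtype=float)
            return np.abs(idx[:, None] - idx[None, :])
        return 1.0 - np.eye(k)

    def symbol_index(self, symbol: str) -> int:
        try:
            return self.state_space.index(symbol)
        except ValueError:
            raise MatrixError(
                f"state symbol {symbol!r} outside state space of character "
                f"{self.char_id}"
            ) from None


@dataclass
class CharacterMatrix:
    """Taxa x characters with per-cell state sets and per-character specs."""

    taxa: list[str]
    cells: list[list[frozenset[str]]]  # [taxon][char] -> set of symbols
    specs: list[CharacterSpec]

    def __post_init__(self):
        if len(set(self.taxa)) != len(self.taxa):
            raise MatrixError("taxon labels must be unique")
        nchar = len(self.specs)
        if len(self.cells) != len(self.taxa):
            raise MatrixError("one row of cells per taxon required")
        for label, row in zip(self.taxa, self.cells):
            if len(row) != nchar:
                raise MatrixError(
                    f"row for {label!r} has {len(row)} cells, expected {nchar}"
                )
        for j, spec in enumerate(self.specs):
            space = set(spec.state_space)
            for label, row in zip(self.taxa, self.cells):
                if not row[j]:
                    raise MatrixError(f"empty state set at ({label!r}, char {j})")
                if not set(row[j]) <= space:
                    raise MatrixError(
                        f"cell ({label!r}, char {j}) uses symbols outside the "
                        f"declared state space"
                    )

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_char(self) -> int:
        return len(self.specs)

    def cell(self, taxon: str, char: int) -> frozenset[str]:
        return self.cells[self.taxa.index(taxon)][char]

    def column(self, char: int) -> dict[str, frozenset[str]]:
        return {t: self.cells[i][char] for i, t in enumerate(self.taxa)}

    def subset_taxa(self, keep: Sequence[str]) -> "CharacterMatrix":
        keep = list(keep)
        idx = {t: i for i, t in enumerate(self.taxa)}
        missing = [t for t in keep if t not in idx]
        if missing:
            raise MatrixError(f"taxa not in matrix: {missing}")
        return CharacterMatrix(
            taxa=keep,
            cells=[list(self.cells[idx[t]]) for t in keep],
            specs=list(self.specs),
        )

    def subset_characters(self, chars: Sequence[int]) -> "CharacterMatrix":
        chars = list(chars)
        specs = []
        for rank, j in enumerate(chars):
            s = self.specs[j]
            specs.append(
                CharacterSpec(rank, s.kind, s.state_space, s.weight, s.cost)
            )
        return CharacterMatrix(
            taxa=list(self.taxa),
            cells=[[row[j] for j in chars] for row in self.cells],
            specs=specs,
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, CharacterMatrix):
            return NotImplemented
        if self.taxa != other.taxa or self.cells != other.cells:
            return False
        if len(self.specs) != len(other.specs):
            return False
        for a, b in zip(self.specs, other.specs):
            if (a.kind, a.state_space) != (b.kind, b.state_space):
                return False
            if abs(a.weight - b.weight) > 1e-12:
                return False
        return True


@dataclass
class AgeTable:
    """Per-taxon first/last appearance datums (Ma) and extant flags.

    Extant taxa are pinned to the present day (FAD = LAD = 0).
    """

    ages: dict[str, tuple[float, float, bool]] = field(default_factory=dict)

    def add(self, taxon: str, fad: float, lad: Optional[float], extant: bool) -> None:
        if extant:
            fad, lad = 0.0, 0.0
        if lad is None:
            lad = fad
        if fad < 0 or lad < 0:
            raise MatrixError(f"negative age for {taxon!r}")
        if lad > fad:
            raise MatrixError(f"LAD exceeds FAD for {taxon!r} ({lad} > {fad})")
        self.ages[taxon] = (float(fad), float(lad), bool(extant))

    def fad(self, taxon: str) -> float:
        try:
            return self.ages[taxon][0]
        except KeyError:
            raise MatrixError(f"taxon {taxon!r} missing from age table") from None

    def lad(self, taxon: str) -> float:
        return self.ages[taxon][1]

    def is_extant(self, taxon: str) -> bool:
        return self.ages[taxon][2]

    def taxa(self) -> list[str]:
        return list(self.ages)

    def __contains__(self, taxon: str) -> bool:
        return taxon in self.ages


# --------------------------------------------------------------------- NEXUS

_BLOCK_RE = re.compile(
    r"BEGIN\s+ASSUMPTIONS\s*;(.*?)END\s*;", re.IGNORECASE | re.DOTALL
)


def _parse_index_list(text: str, nchar: int) -> list[int]:
    """NEXUS 1-based character lists: '1 3-5 8' -> [0, 2, 3, 4, 7]."""
    out: list[int] = []
    for token in text.replace(",", " ").split():
        if "-" in token:
            lo, hi = token.split("-")
            hi = nchar if hi.strip() == "." else int(hi)
            out.extend(range(int(lo) - 1, hi))
        elif token == "ALL":
            out.extend(range(nchar))
        else:
            out.append(int(token) - 1)
    bad = [i for i in out if i < 0 or i >= nchar]
    if bad:
        raise MatrixError(f"character index out of range in ASSUMPTIONS: {bad}")
    return out


def _parse_assumptions(text: str, nchar: int):
    kinds = {}
    weights = {}
    m = _BLOCK_RE.search(text)
    if not m:
        return kinds, weights
    body = m.group(1)
    for stmt in body.split(";"):
        stmt = stmt.strip()
        if not stmt:
            continue
        head, _, rest = stmt.partition("=")
        name = head.split()[0].upper()
        if name not in ("TYPESET", "WTSET"):
            continue
        for clause in rest.split(","):
            clause = clause.strip()
            if not clause:
                continue
            key, _, members = clause.partition(":")
            key = key.strip()
            idx = _parse_index_list(members, nchar)
            if name == "TYPESET":
                kind = {"ORD": "ordered", "UNORD": "unordered", "IRREV": "irreversible"}.get(
                    key.upper()
                )
                if kind is None:
                    raise MatrixError(f"unsupported character type {key!r} in TYPESET")
                for i in idx:
                    kinds[i] = kind
            else:
                try:
                    w = float(key)
                except ValueError:
                    raise MatrixError(f"non-numeric weight {key!r} in WTSET") from None
                for i in idx:
                    weights[i] = w
    return kinds, weights


def read_nexus(path_or_text) -> CharacterMatrix:
    """Read a NEXUS DATA/CHARACTERS block (plus optional ASSUMPTIONS).

    Polymorphisms '{01}' become multi-symbol state sets; '?' and '-' become the
    full declared state space.  TYPESET (ord/unord) and WTSET entries in an
    ASSUMPTIONS block are applied; characters default to unordered, weight 1.
    """
    text = _slurp(path_or_text)
    try:
        dmat = dendropy.StandardCharacterMatrix.get(data=text, schema="nexus")
    except Exception as exc:
        raise MatrixError(f"NEXUS parse error: {exc}") from exc

    symbols = tuple(
        s.symbol
        for s in dmat.default_state_alphabet.fundamental_state_iter()
        if s.symbol not in ("-",)
    )
    full = frozenset(symbols)
    taxa = [t.label for t in dmat.taxon_namespace]
    lengths = {len(dmat[t]) for t in dmat.taxon_namespace}
    if len(lengths) != 1:
        raise MatrixError(f"rows of unequal length: {sorted(lengths)}")
    nchar = lengths.pop()

    cells: list[list[frozenset[str]]] = []
    for t in dmat.taxon_namespace:
        row = []
        for state in dmat[t]:
            fundamentals = {s.symbol for s in state.fundamental_states}
            if state.symbol in ("?", "-") or "-" in fundamentals:
                row.append(full)
            else:
                row.append(frozenset(fundamentals))
        cells.append(row)

    kinds, weights = _parse_assumptions(text, nchar)
    specs = [
        CharacterSpec(
            char_id=j,
            kind=kinds.get(j, "unordered"),
            state_space=symbols,
            weight=weights.get(j, 1.0),
        )
        for j in range(nchar)
    ]
    return CharacterMatrix(taxa=taxa, cells=cells, specs=specs)


def write_nexus(matrix: CharacterMatrix, path=None) -> str:
    """Serialize a matrix to NEXUS; returns the text (and writes it if given a
    path).  Ordered characters and non-unit weights go to an ASSUMPTIONS block."""
    symbols: list[str] = []
    for spec in matrix.specs:
        for s in spec.state_space:
            if s not in symbols:
                symbols.append(s)
    full_by_char = [frozenset(spec.state_space) for spec in matrix.specs]

    width = max((len(t) for t in matrix.taxa), default=1) + 2
    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_char};",
        f"FORMAT DATATYPE=STANDARD SYMBOLS=\"{''.join(symbols)}\" MISSING=? GAP=-;",
        "MATRIX",
    ]
    for label, row in zip(matrix.taxa, matrix.cells):
        chunks = []
        for j, cell in enumerate(row):
            if cell == full_by_char[j]:
                chunks.append("?")
            elif len(cell) == 1:
                chunks.append(next(iter(cell)))
            else:
                chunks.append("{" + "".join(sorted(cell)) + "}")
        name = f"'{label}'" if " " in label else label
        lines.append(f"{name:<{width}}{''.join(chunks)}")
    lines += [";", "END;"]

    ordered = [j + 1 for j, s in enumerate(matrix.specs) if s.kind == "ordered"]
    irrev = [j + 1 for j, s in enumerate(matrix.specs) if s.kind == "irreversible"]
    if irrev:
        raise MatrixError("irreversible characters cannot be written to NEXUS")
    wtclauses: dict[float, list[int]] = {}
    for j, s in enumerate(matrix.specs):
        wtclauses.setdefault(s.weight, []).append(j + 1)
    need_wtset = set(wtclauses) != {1.0}
    if ordered or need_wtset:
        lines.append("BEGIN ASSUMPTIONS;")
        if ordered:
            lines.append(
                "TYPESET * default = ord: "
                + " ".join(map(str, ordered))
                + ";"
            )
        if need_wtset:
            clauses = ", ".join(
                f"{w:g}: " + " ".join(map(str, idx)) for w, idx in wtclauses.items()
            )
            lines.append(f"WTSET * weights = {clauses};")
        lines.append("END;")
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


# -------------------------------------------------------------------- Newick


def read_newick(path_or_text) -> PhyloTree:
    return PhyloTree.from_newick(_slurp(path_or_text))


def write_newick(tree: PhyloTree, path=None) -> str:
    text = tree.to_newick()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text


def read_newick_list(path_or_text) -> list[PhyloTree]:
    text = _slurp(path_or_text)
    return [
        PhyloTree.from_newick(chunk + ";")
        for chunk in text.split(";")
        if chunk.strip()
    ]


# ---------------------------------------------------------------- age tables


def read_age_table(path_or_text) -> AgeTable:
    """Delimited (comma or tab, sniffed) table: taxon, FAD, LAD, extant.

    Extant taxa are forced to the present day.  Validation failures report
    every offending row.
    """
    text = _slurp(path_or_text)
    df = pd.read_csv(io.StringIO(text), sep=None, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"taxon", "fad", "lad", "extant"}
    if not required <= set(df.columns):
        raise MatrixError(
            f"age table must have columns taxon,FAD,LAD,extant; got {list(df.columns)}"
        )
    table = AgeTable()
    problems = []
    for _, row in df.iterrows():
        taxon = str(row["taxon"]).strip()
        extant = str(row["extant"]).strip().lower() in ("true", "1", "yes", "t")
        fad = row["fad"]
        lad = row["lad"]
        fad = None if pd.isna(fad) else float(fad)
        lad = None if pd.isna(lad) else float(lad)
        if extant:
            table.add(taxon, 0.0, 0.0, True)
            continue
        if fad is None:
            problems.append(f"{taxon}: non-extant taxon lacks a FAD")
            continue
        try:
            table.add(taxon, fad, lad, False)
        except MatrixError as exc:
            problems.append(str(exc))
    if problems:
        raise MatrixError("invalid age table rows: " + "; ".join(problems))
    return table


def interval_midpoint_age(oldest: float, youngest: float) -> float:
    """Midpoint of a reported stratigraphic interval, in Ma."""
    if youngest < 0 or oldest < youngest:
        raise MatrixError(f"reversed or negative interval ({oldest}, {youngest})")
    return (oldest + youngest) / 2.0


# ------------------------------------------------------------- gap coding


def read_fasta_alignment(path_or_text) -> dict[str, str]:
    text = _slurp(path_or_text)
    seqs: dict[str, str] = {}
    name = None
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            name = line[1:].split()[0]
            seqs[name] = ""
        elif name is not None:
            seqs[name] += line
    if not seqs:
        raise MatrixError("no sequences in FASTA input")
    return seqs


def _gap_spans(seq: str) -> list[tuple[int, int]]:
    spans = []
    start = None
    for i, ch in enumerate(seq):
        if ch == "-":
            if start is None:
                start = i
        elif start is not None:
            spans.append((start, i - 1))
            start = None
    if start is not None:
        spans.append((start, len(seq) - 1))
    return spans


def simple_gap_code(alignment: dict[str, str]) -> CharacterMatrix:
    """Simple indel coding: one binary character per distinct gap span.

    A taxon scores 1 (present) if it has exactly that gap, '?' (unknowable) if
    one of its gaps strictly contains the span, and 0 (absent) otherwise.
    """
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) > 1:
        raise MatrixError("ragged alignment: sequences differ in length")
    spans_by_taxon = {t: set(_gap_spans(s)) for t, s in alignment.items()}
    all_spans = sorted({sp for spans in spans_by_taxon.values() for sp in spans})

    taxa = list(alignment)
    full = frozenset({"0", "1"})
    cells: list[list[frozenset[str]]] = [[] for _ in taxa]
    for span in all_spans:
        lo, hi = span
        for i, t in enumerate(taxa):
            if span in spans_by_taxon[t]:
                cells[i].append(frozenset({"1"}))
            elif any(a <= lo and hi <= b and (a, b) != span
                     for a, b in spans_by_taxon[t]):
                cells[i].append(full)
            else:
                cells[i].append(frozenset({"0"}))
    specs = [
        CharacterSpec(char_id=j, kind="unordered", state_space=("0", "1"))
        for j in range(len(all_spans))
    ]
    return CharacterMatrix(taxa=taxa, cells=cells, specs=specs)


# ------------------------------------------------------------------ helpers


def _slurp(path_or_text) -> str:
    text = str(path_or_text)
    if "\n" not in text and not text.strip().startswith(("(", "#", ">")):
        with open(text) as fh:
            return fh.read()
    return text
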