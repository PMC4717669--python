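"""Core domain types: chromosome structures, operations and weight schemes.

A chromosome structure is a finite collection of linear and circular
chromosomes, each an ordered sequence of signed genes.  Genes are named by a
family identifier and an optional paralog index (rendered ``fam.3``); the
orientation records the strand.  Gene lengths and intergenic content are
deliberately abstracted away.

Two text dialects are supported: a GRIMM-like machine format (``-`` prefix for
the reverse strand, ``$`` linear / ``@`` circular terminators, ``>name``
headers) and a table dialect used by printed gene-order tables (``*`` prefix
for the complementary strand, ``|`` between chromosomes, trailing ``(C)`` /
``(L)`` topology markers).
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Optional, Sequence, Union

__all__ = [
    "GeneToken",
    "Chromosome",
    "ChromosomeStructure",
    "WeightScheme",
    "OpKind",
    "OperationRecord",
    "Dialect",
    "Pattern",
    "ParseError",
    "parse_structure",
    "write_structure",
    "validate_weights",
    "linear_chromosome",
    "circular_chromosome",
    "structure",
    "CIRCULAR_DEFAULT_WEIGHTS",
    "LINEAR_DEFAULT_WEIGHTS",
    "UNIT_WEIGHTS",
    "case2_weights",
]


class Dialect(str, enum.Enum):
    GRIMM = "grimm"
    TABLE1 = "table1"


class Pattern(str, enum.Enum):
    CIRCULAR = "circular"
    LINEAR = "linear"
    NONE = "none"


class ParseError(ValueError):
    """Malformed gene-order text; carries line and column of the offence."""

    def __init__(self, message: str, line: int = 0, column: int = 0):
        super().__init__(f"line {line}, column {column}: {message}")
        self.line = line
        self.column = column


@dataclass(frozen=True, order=True)
class GeneToken:
    """One signed gene occurrence: family name, optional paralog index, strand."""

    family: str
    paralog: Optional[int] = None
    orient: int = 1

    def __post_init__(self):
        if not self.family:
            raise ValueError("gene family must be non-empty")
        if self.paralog is not None and self.paralog < 1:
            raise ValueError("paralog index must be >= 1")
        if self.orient not in (1, -1):
            raise ValueError("orientation must be +1 or -1")

    @property
    def key(self) -> tuple:
        return (self.family, self.paralog or 0)

    def flipped(self) -> "GeneToken":
        return GeneToken(self.family, self.paralog, -self.orient)

    def __str__(self) -> str:
        name = self.family if self.paralog is None else f"{self.family}.{self.paralog}"
        return name if self.orient > 0 else "-" + name

    # sort key must not compare None with int
    def _sort_key(self):
        return (self.family, self.paralog or 0, self.orient)


def _canonical_linear(genes: tuple) -> tuple:
    rev = tuple(g.flipped() for g in reversed(genes))
    fwd_k = tuple(g._sort_key() for g in genes)
    rev_k = tuple(g._sort_key() for g in rev)
    return genes if fwd_k <= rev_k else rev


def _canonical_circular(genes: tuple) -> tuple:
    best = None
    best_key = None
    for seq in (genes, tuple(g.flipped() for g in reversed(genes))):
        for i in range(len(seq)):
            rot = seq[i:] + seq[:i]
            key = tuple(g._sort_key() for g in rot)
            if best_key is None or key < best_key:
                best, best_key = rot, key
    return best


@dataclass(frozen=True)
class Chromosome:
    """An ordered, non-empty run of signed genes, linear or circular.

    Equality and hashing use the canonical reading: circular chromosomes
    compare equal under rotation and under full reversal with strand flip;
    linear chromosomes under full reversal with strand flip.
    """

    genes: tuple
    circular: bool = False

    def __post_init__(self):
        if not self.genes:
            raise ValueError("chromosome must contain at least one gene")
        object.__setattr__(self, "genes", tuple(self.genes))

    def canonical(self) -> "Chromosome":
        canon = (_canonical_circular if self.circular else _canonical_linear)(self.genes)
        return Chromosome(canon, self.circular)

    @property
    def canonical_key(self) -> tuple:
        c = self.canonical()
        return (c.circular, tuple(g._sort_key() for g in c.genes))

    def __eq__(self, other):
        if not isinstance(other, Chromosome):
            return NotImplemented
        return self.canonical_key == other.canonical_key

    def __hash__(self):
        return hash(self.canonical_key)

    def __len__(self):
        return len(self.genes)


@dataclass(frozen=True)
class ChromosomeStructure:
    """A multiset of chromosomes; the central object all algorithms act on."""

    chromosomes: tuple
    name: str = ""

    def __post_init__(self):
        object.__setattr__(self, "chromosomes", tuple(self.chromosomes))
        seen = {}
        for c in self.chromosomes:
            for g in c.genes:
                if g.key in seen and g.paralog is not None:
                    raise ValueError(f"duplicate gene {g.family}.{g.paralog}")
                seen.setdefault(g.key, 0)

    def canonical(self) -> "ChromosomeStructure":
        chroms = sorted((c.canonical() for c in self.chromosomes),
                        key=lambda c: c.canonical_key)
        return ChromosomeStructure(tuple(chroms), self.name)

    @property
    def canonical_key(self) -> tuple:
        return tuple(sorted(c.canonical_key for c in self.chromosomes))

    def __eq__(self, other):
        if not isinstance(other, ChromosomeStructure):
            return NotImplemented
        return self.canonical_key == other.canonical_key

    def __hash__(self):
        return hash(self.canonical_key)

    def gene_keys(self) -> list:
        return [g.key for c in self.chromosomes for g in c.genes]

    def families(self) -> set:
        return {g.family for c in self.chromosomes for g in c.genes}

    @property
    def n_genes(self) -> int:
        return sum(len(c) for c in self.chromosomes)

    @property
    def n_linear(self) -> int:
        return sum(1 for c in self.chromosomes if not c.circular)


def linear_chromosome(*names: str) -> Chromosome:
    return Chromosome(tuple(_token_from_name(n) for n in names), circular=False)


def circular_chromosome(*names: str) -> Chromosome:
    return Chromosome(tuple(_token_from_name(n) for n in names), circular=True)


def structure(*chroms: Chromosome, name: str = "") -> ChromosomeStructure:
    return ChromosomeStructure(tuple(chroms), name)


_TOKEN_RE = re.compile(r"^([*-]?)([A-Za-z0-9_']+?)(?:\.(\d+))?$")


def _token_from_name(text: str, line: int = 0, col: int = 0) -> GeneToken:
    m = _TOKEN_RE.match(text)
    if not m:
        raise ParseError(f"malformed gene token {text!r}", line, col)
    sign, family, pidx = m.groups()
    return GeneToken(family, int(pidx) if pidx else None, -1 if sign else 1)


def parse_structure(text: str, dialect: Union[Dialect, str] = Dialect.GRIMM,
                    name: str = "") -> ChromosomeStructure:
    """Parse gene-order text in the given dialect into a structure.

    GRIMM dialect: optional ``>name`` header, one chromosome per line, tokens
    whitespace-separated, ``-`` prefix = reverse strand, line ends with ``$``
    (linear) or ``@`` (circular).  Table dialect: ``*`` prefix = reverse
    strand, ``|`` separates chromosomes, each chromosome ends with ``(C)`` or
    ``(L)``.
    """
    dialect = Dialect(dialect)
    if dialect is Dialect.GRIMM:
        return _parse_grimm(text, name)
    return _parse_table(text, name)


def _check_duplicates(chroms, line=0):
    seen = set()
    for c in chroms:
        for g in c.genes:
            if g.key in seen:
                raise ParseError(f"duplicate gene {g.family}"
                                 + (f".{g.paralog}" if g.paralog else ""), line, 0)
            seen.add(g.key)


def _parse_grimm(text: str, name: str) -> ChromosomeStructure:
    chroms = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        stripped = raw.strip()
        if not stripped or stripped.startswith("#"):
            continue
        if stripped.startswith(">"):
            name = stripped[1:].strip() or name
            continue
        parts = stripped.split()
        if parts[-1] not in ("$", "@"):
            raise ParseError("chromosome line must end with '$' or '@'", lineno,
                             len(raw))
        circular = parts[-1] == "@"
        tokens = [_token_from_name(p, lineno, i) for i, p in enumerate(parts[:-1])]
        if not tokens:
            raise ParseError("empty chromosome", lineno, 0)
        chroms.append(Chromosome(tuple(tokens), circular))
    _check_duplicates(chroms)
    return ChromosomeStructure(tuple(chroms), name)


def _parse_table(text: str, name: str) -> ChromosomeStructure:
    chroms = []
    body = text.strip()
    if not body:
        return ChromosomeStructure((), name)
    for segno, segment in enumerate(body.split("|"), start=1):
        seg = segment.strip()
        m = re.search(r"\((C|L)\)\s*$", seg)
        if not m:
            raise ParseError("chromosome must end with '(C)' or '(L)'", segno,
                             len(seg))
        circular = m.group(1) == "C"
        toks = seg[:m.start()].split()
        if not toks:
            raise ParseError("empty chromosome", segno, 0)
        genes = []
        for i, t in enumerate(toks):
            if t.startswith("*"):
                g = _token_from_name(t[1:], segno, i)
                genes.append(g.flipped())
            else:
                genes.append(_token_from_name(t, segno, i))
        chroms.append(Chromosome(tuple(genes), circular))
    _check_duplicates(chroms)
    return ChromosomeStructure(tuple(chroms), name)


def write_structure(s: ChromosomeStructure,
                    dialect: Union[Dialect, str] = Dialect.GRIMM) -> str:
    """Serialize a structure in canonical, deterministic form."""
    dialect = Dialect(dialect)
    s = s.canonical()
    if dialect is Dialect.GRIMM:
        lines = [f">{s.name}"]
        for c in s.chromosomes:
            toks = " ".join(str(g) for g in c.genes)
            lines.append(f"{toks} {'@' if c.circular else '$'}")
        return "\n".join(lines) + "\n"
    segments = []
    for c in s.chromosomes:
        toks = " ".join(
            ("*" if g.orient < 0 else "")
            + (g.family if g.paralog is None else f"{g.family}.{g.paralog}")
            for g in c.genes)
        segments.append(f"{toks} ({'C' if c.circular else 'L'})")
    return " | ".join(segments)


class OpKind(str, enum.Enum):
    DOUBLE = "double"           # double-cut-and-paste (DCJ)
    SESQUI = "sesqui"           # sesqui-cut-and-paste
    CUTJOIN = "cutjoin"         # cut or join of a single adjacency
    DELETE_REGION = "delete"    # deletion of a maximal special region
    INSERT_REGION = "insert"    # insertion of a special region


@dataclass
class OperationRecord:
    """One rearrangement event in an emitted scenario."""

    kind: OpKind
    operands: tuple
    weight: Fraction
    structure_after: Optional[ChromosomeStructure] = None


@dataclass(frozen=True)
class WeightScheme:
    """The six operation weights plus the declared descent pattern.

    ``delete`` is the weight of removing a maximal region of genes private to
    the source structure (graph a-node deletion); ``insert`` the weight of
    inserting a region of genes private to the target (graph b-node deletion,
    the symbol c of the exactness condition d <= c <= 2d).  Weights are exact
    rationals so that rule selection never hinges on float ties.
    """

    double: Fraction
    sesqui: Fraction
    cut: Fraction
    join: Fraction
    delete: Fraction
    insert: Fraction
    pattern: Pattern = Pattern.NONE

    def __post_init__(self):
        for f in ("double", "sesqui", "cut", "join", "delete", "insert"):
            object.__setattr__(self, f, Fraction(getattr(self, f)))
        object.__setattr__(self, "pattern", Pattern(self.pattern))

    def of(self, kind: OpKind) -> Fraction:
        return {
            OpKind.DOUBLE: self.double,
            OpKind.SESQUI: self.sesqui,
            OpKind.DELETE_REGION: self.delete,
            OpKind.INSERT_REGION: self.insert,
        }.get(kind) if kind is not OpKind.CUTJOIN else None

    @property
    def standard_uniform(self) -> Optional[Fraction]:
        """The common weight d if all operations except insertion share one."""
        vals = {self.double, self.sesqui, self.cut, self.join, self.delete}
        return next(iter(vals)) if len(vals) == 1 else None

    @property
    def is_case2(self) -> bool:
        d = self.standard_uniform
        return d is not None and d <= self.insert <= 2 * d

    def as_dict(self) -> dict:
        return {f: float(getattr(self, f))
                for f in ("double", "sesqui", "cut", "join", "delete", "insert")}


def validate_weights(w: WeightScheme) -> list:
    """Check positivity and the pattern's non-increasing weight order.

    Returns a list of violation strings (empty iff the scheme is valid for its
    declared pattern).  The descent is inexact: equalities are allowed.
    """
    violations = []
    for f in ("double", "sesqui", "cut", "join", "delete", "insert"):
        if getattr(w, f) <= 0:
            violations.append(f"weight {f} must be strictly positive")
    if violations:
        return violations
    if w.pattern is Pattern.CIRCULAR:
        order = [("insert", w.insert), ("sesqui", w.sesqui), ("join", w.join),
                 ("double", w.double), ("delete", w.delete)]
    elif w.pattern is Pattern.LINEAR:
        order = [("insert", w.insert), ("double", w.double), ("sesqui", w.sesqui),
                 ("cut", w.cut), ("delete", w.delete)]
    else:
        order = []
    for (n1, v1), (n2, v2) in zip(order, order[1:]):
        if v1 < v2:
            violations.append(
                f"pattern {w.pattern.value}: weight {n1} ({v1}) < {n2} ({v2})")
    return violations


# Default weight values, assigned in the pattern's descent order; the
# operation missing from a pattern's list receives the remaining value.
CIRCULAR_DEFAULT_WEIGHTS = WeightScheme(
    insert=Fraction(3, 2), sesqui=Fraction(6, 5), join=Fraction(11, 10),
    double=Fraction(1), delete=Fraction(9, 10), cut=Fraction(4, 5),
    pattern=Pattern.CIRCULAR)

LINEAR_DEFAULT_WEIGHTS = WeightScheme(
    insert=Fraction(3, 2), double=Fraction(6, 5), sesqui=Fraction(11, 10),
    cut=Fraction(1), delete=Fraction(9, 10), join=Fraction(4, 5),
    pattern=Pattern.LINEAR)

UNIT_WEIGHTS = WeightScheme(1, 1, 1, 1, 1, 1, Pattern.NONE)


def case2_weights(c=Fraction(3, 2), d=Fraction(1)) -> WeightScheme:
    """Uniform standard weight d with insertion weight c (exact when d<=c<=2d)."""
    return WeightScheme(d, d, d, d, d, c, Pattern.NONE)
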