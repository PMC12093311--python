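"""Gene set data model, GMT I/O, and gene symbol validation.

A gene set is a named collection of gene symbols sharing a biological
function (a pathway, process, or cellular component).  Collections of gene
sets plus a background universe form a gene set database, the unit that
overrepresentation analysis consumes.  Symbols are normalized to uppercase
HGNC-style abbreviations before any comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence


class GmtParseError(ValueError):
    """Raised for malformed GMT content; names the offending line."""


def normalize_symbol(symbol: str) -> str:
    """Uppercase and strip a gene symbol for comparison."""
    return symbol.strip().upper()


def dedup_symbols(symbols: Iterable[str]) -> tuple[list[str], int]:
    """Collapse case-insensitive duplicates keeping first occurrence.

    Returns the normalized, order-preserving unique list and the number of
    duplicates removed.  Duplicate symbols from a language model are a
    quality signal, so the count is always surfaced, never silently lost.
    """
    seen: set[str] = set()
    out: list[str] = []
    n_dup = 0
    for raw in symbols:
        sym = normalize_symbol(raw)
        if not sym:
            continue
        if sym in seen:
            n_dup += 1
        else:
            seen.add(sym)
            out.append(sym)
    return out, n_dup


@dataclass
class GeneSet:
    """A named gene set: free-text description plus member symbols.

    Members are deduplicated case-insensitively on construction;
    ``n_duplicates`` records how many were collapsed.  An empty member
    list is allowed (flagged via ``is_empty``), since generation can
    legitimately fail to produce genes.
    """

    description: str
    genes: list[str]
    n_duplicates: int = 0

    def __post_init__(self) -> None:
        self.description = self.description.strip()
        if not self.description:
            raise ValueError("gene set description must be non-empty")
        unique, n_dup = dedup_symbols(self.genes)
        self.genes = unique
        self.n_duplicates += n_dup

    @property
    def is_empty(self) -> bool:
        return not self.genes

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GeneSetDatabase:
    """A keyed collection of gene sets with a background gene universe.

    ``universe`` defaults to the union of all member genes.  When an
    explicit universe is supplied, construction fails if any member gene
    falls outside it, reporting the out-of-universe symbols.
    """

    sets: dict[str, GeneSet]
    universe: set[str]
    source_label: str = ""

    def __init__(
        self,
        sets: Iterable[GeneSet],
        universe: Iterable[str] | None = None,
        source_label: str = "",
    ) -> None:
        keyed: dict[str, GeneSet] = {}
        for gs in sets:
            if gs.description in keyed:
                raise ValueError(f"duplicate gene set description: {gs.description!r}")
            keyed[gs.description] = gs
        self.sets = keyed
        union = {g for gs in keyed.values() for g in gs.genes}
        if universe is None:
            self.universe = union
        else:
            self.universe = {normalize_symbol(g) for g in universe}
            stray = sorted(union - self.universe)
            if stray:
                head = ", ".join(stray[:10])
                raise ValueError(
                    f"{len(stray)} member gene(s) outside the supplied universe: {head}"
                )
        self.source_label = source_label

    @property
    def descriptions(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, description: str) -> bool:
        return description in self.sets

    def __getitem__(self, description: str) -> GeneSet:
        return self.sets[description]


@dataclass
class SymbolTable:
    """Approved gene symbols plus an optional alias -> approved mapping."""

    approved: set[str]
    aliases: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.approved = {normalize_symbol(s) for s in self.approved}
        norm_aliases: dict[str, str] = {}
        for alias, target in self.aliases.items():
            target_n = normalize_symbol(target)
            if target_n not in self.approved:
                raise ValueError(f"alias target {target!r} not in approved symbols")
            norm_aliases[normalize_symbol(alias)] = target_n
        self.aliases = norm_aliases

    def resolve(self, symbol: str) -> str | None:
        """Map a raw symbol to its approved form, or None if unknown."""
        sym = normalize_symbol(symbol)
        if sym in self.approved:
            return sym
        return self.aliases.get(sym)

    def __contains__(self, symbol: str) -> bool:
        return self.resolve(symbol) is not None

    def __len__(self) -> int:
        return len(self.approved)


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of validating a symbol list against a symbol table.

    ``fraction_valid`` is n_valid over the number of unique case-normalized
    inputs — the statistic used to measure how often a model emits approved
    nomenclature.  ``n_duplicates`` counts case-insensitive repeats in the
    input, a separate model-quality signal.
    """

    n_input: int
    n_valid: int
    n_invalid: int
    n_duplicates: int
    invalid_symbols: tuple[str, ...]
    fraction_valid: float
    empty_input: bool = False


def validate_symbols(genes: Sequence[str], table: SymbolTable) -> ValidationReport:
    """Validate gene symbols case-insensitively against approved symbols.

    Aliases (when present in the table) count as valid.  Duplicates are
    counted after case normalization; invalid symbols are reported in
    input order.
    """
    if len(table) == 0:
        raise ValueError("symbol table is empty")
    unique, n_dup = dedup_symbols(genes)
    invalid = [s for s in unique if s not in table]
    n_valid = len(unique) - len(invalid)
    return ValidationReport(
        n_input=len(genes),
        n_valid=n_valid,
        n_invalid=len(invalid),
        n_duplicates=n_dup,
        invalid_symbols=tuple(invalid),
        # an empty input has nothing invalid in it: fraction defined as 1
        fraction_valid=1.0 if not unique else n_valid / len(unique),
        empty_input=len(genes) == 0,
    )


# ---------------------------------------------------------------------------
# GMT I/O — tab-separated, one set per line: name, description, genes...
# The second field is written as "na" when no separate description exists,
# matching the dominant dialect of common gene set libraries.
# ---------------------------------------------------------------------------

def read_gmt(
    path: str | Path,
    universe: Iterable[str] | None = None,
    source_label: str | None = None,
) -> GeneSetDatabase:
    """Read a GMT file into a database.

    Each non-empty line must have at least two tab-separated fields.
    Duplicate genes within a line are collapsed with the count recorded on
    the set; duplicate set names across lines are an error.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise GmtParseError(
                    f"{path.name}:{lineno}: expected >=2 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name = fields[0].strip()
            if not name:
                raise GmtParseError(f"{path.name}:{lineno}: empty set name")
            genes = [g for g in fields[2:] if g.strip()]
            sets.append(GeneSet(description=name, genes=genes))
    try:
        return GeneSetDatabase(
            sets,
            universe=universe,
            source_label=source_label if source_label is not None else path.name,
        )
    except ValueError as exc:
        raise GmtParseError(f"{path.name}: {exc}") from exc


def write_gmt(db: GeneSetDatabase, path: str | Path) -> None:
    """Write a database to GMT; round-trips names and memberships exactly.

    Refuses to emit symbols or names containing tabs or newlines, which
    would produce ambiguous GMT.
    """
    path = Path(path)
    lines = []
    for gs in db.sets.values():
        for token in (gs.description, *gs.genes):
            if "\t" in token or "\n" in token:
                raise ValueError(
                    f"cannot write GMT: field {token!r} contains a tab or newline"
                )
        lines.append("\t".join([gs.description, "na", *gs.genes]))
    path.write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


def read_symbol_table(path: str | Path) -> SymbolTable:
    """Read a 1- or 2-column TSV of approved symbols (symbol[, alias]).

    With two columns, the second column is an alias mapped to the approved
    symbol in the first column.  A header line starting with '#' is skipped.
    """
    approved: set[str] = set()
    aliases: dict[str, str] = {}
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            approved.add(fields[0])
            if len(fields) > 1 and fields[1].strip():
                aliases[fields[1]] = fields[0]
    return SymbolTable(approved=approved, aliases=aliases)


def write_symbol_table(table: SymbolTable, path: str | Path) -> None:
    # alias rows repeat the approved symbol in column 1 per the TSV contract
    out = sorted(table.approved)
    out += [f"{target}\t{alias}" for alias, target in sorted(table.aliases.items())]
    Path(path).write_text("\n".join(out) + ("\n" if out else ""), encoding="utf-8")
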