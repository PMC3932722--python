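"""Core record types shared across the pipeline.

The pipeline deals with four kinds of external data: drugs and their
protein targets, ATC classification codes, gene-set collections for
pathway enrichment, and per-drug literature co-occurrence counts. Each
is represented by a small frozen-ish dataclass with explicit validation
so that file readers and simulators share one contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

KNOWN_GROUPS = frozenset(
    {"approved", "illicit", "experimental", "withdrawn", "nutraceutical", "investigational"}
)

NIDA_CATEGORIES = (
    "depressants",
    "dissociative anesthetics",
    "hallucinogens",
    "opioids and morphine derivatives",
    "stimulants",
    "other compounds",
)

#: Category used for drugs that are not on the addictive list.
NIDA_NONE = "none"


class FormatError(ValueError):
    """A file does not conform to its documented layout."""


class IntegrityError(ValueError):
    """Data violates an internal invariant (duplicates, impossible counts)."""


@dataclass
class DrugRecord:
    """One drug: identity, legal status, addiction category, ATC codes, targets.

    ``nida_category`` is ``"none"`` exactly when the drug is not on the
    addictive list. ``target_count`` is carried separately from ``targets``
    because the packaged reference table records how many targets each drug
    has without naming them.
    """

    drug_id: str
    name: str
    groups: set[str] = field(default_factory=set)
    nida_category: str = NIDA_NONE
    atc_codes: set[str] = field(default_factory=set)
    targets: set[str] = field(default_factory=set)
    target_count: int | None = None

    @property
    def is_addictive(self) -> bool:
        return self.nida_category != NIDA_NONE

    @property
    def n_targets(self) -> int:
        """Declared target count if present, else the size of the target set."""
        if self.target_count is not None:
            return self.target_count
        return len(self.targets)

    def atc_level1(self) -> set[str]:
        """Anatomical main groups: the first letter of each ATC code."""
        return {code[0] for code in self.atc_codes if code}


@dataclass
class TargetRecord:
    """A drug target identified by its gene symbol."""

    gene_symbol: str
    gene_id: int | None = None
    uniprot_id: str | None = None


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. canonical pathways), keyed by set id."""

    sets: dict[str, set[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def add(self, set_id: str, genes: set[str], description: str = "") -> None:
        if set_id in self.sets:
            raise IntegrityError(f"duplicate gene set id: {set_id!r}")
        if not genes:
            raise IntegrityError(f"gene set {set_id!r} is empty")
        self.sets[set_id] = set(genes)
        self.descriptions[set_id] = description

    def __len__(self) -> int:
        return len(self.sets)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return self.sets == other.sets and self.descriptions == other.descriptions

    def universe(self) -> set[str]:
        out: set[str] = set()
        for genes in self.sets.values():
            out |= genes
        return out


@dataclass
class LiteratureCountRow:
    """PubMed-style counts for one drug.

    ``n_drug``: abstracts mentioning the drug; ``n_keyword``: abstracts
    mentioning at least one addiction-related keyword; ``n_both``: abstracts
    mentioning both.
    """

    drug_id: str
    n_drug: int
    n_keyword: int
    n_both: int

    def validate(self, corpus_total: int) -> None:
        if min(self.n_drug, self.n_keyword, self.n_both) < 0:
            raise IntegrityError(f"{self.drug_id}: negative count")
        if self.n_both > min(self.n_drug, self.n_keyword):
            raise IntegrityError(
                f"{self.drug_id}: n_both={self.n_both} exceeds a margin "
                f"(n_drug={self.n_drug}, n_keyword={self.n_keyword})"
            )
        if max(self.n_drug, self.n_keyword) > corpus_total:
            raise IntegrityError(f"{self.drug_id}: margin exceeds corpus total")


#: Number of abstract records in the 2012 PubMed baseline.
PUBMED_2012_TOTAL = 21_508_439


@dataclass
class LiteratureCountTable:
    """Co-occurrence count rows plus the corpus size they refer to."""

    corpus_total: int = PUBMED_2012_TOTAL
    rows: list[LiteratureCountRow] = field(default_factory=list)

    def validate(self) -> None:
        if self.corpus_total <= 0:
            raise IntegrityError("corpus_total must be positive")
        seen: set[str] = set()
        for row in self.rows:
            if row.drug_id in seen:
                raise IntegrityError(f"duplicate drug_id in count table: {row.drug_id}")
            seen.add(row.drug_id)
            row.validate(self.corpus_total)
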