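"""Role-labelled cancer gene catalogue and per-domain cancer-role classification.

Tumour-suppressor (TSG) and oncogene (OCG) symbol lists are merged into a
non-redundant catalogue; genes present in both lists are dual-role.  After
attaching gene -> domain annotations, every domain family in the annotation
universe is classified by the roles of its associated genes:

* ``TSG_SPECIFIC`` — only tumour suppressors carry the domain (ratio 1),
* ``OCG_SPECIFIC`` — only oncogenes carry it (ratio 0),
* ``DUAL_ROLE``    — both roles are represented (ratio strictly in (0,1)),
* ``UNKNOWN``      — the domain has no associated cancer gene (ratio undefined,
  rendered ``"Not available"``).

The dual-role ratio is #associated TSGs / (#associated TSGs + #associated
OCGs).  A dual-role *gene* counts toward both tallies of each of its domains
(policy configurable via ``dual_counts_both``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional

from crossddi.core_io import ValidationError, strip_version

logger = logging.getLogger(__name__)

TSG = "TSG"
OCG = "OCG"
DUAL = "DUAL"

TSG_SPECIFIC = "TSG_SPECIFIC"
OCG_SPECIFIC = "OCG_SPECIFIC"
DUAL_ROLE = "DUAL_ROLE"
UNKNOWN = "UNKNOWN"

NOT_AVAILABLE = "Not available"


@dataclass(frozen=True)
class CancerGene:
    gene_symbol: str
    role: str  # TSG | OCG | DUAL
    domain_accs: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.role not in (TSG, OCG, DUAL):
            raise ValidationError(f"{self.gene_symbol}: unknown role {self.role!r}")


class CancerCatalog:
    """Mapping of gene symbol -> :class:`CancerGene`, ordered by symbol."""

    def __init__(self, genes: Iterable[CancerGene]):
        self._genes: dict[str, CancerGene] = {}
        for g in genes:
            if g.gene_symbol in self._genes:
                raise ValidationError(f"duplicate gene symbol {g.gene_symbol!r}")
            self._genes[g.gene_symbol] = g
        self._genes = dict(sorted(self._genes.items()))

    def __len__(self) -> int:
        return len(self._genes)

    def __iter__(self):
        return iter(self._genes.values())

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._genes

    def __getitem__(self, symbol: str) -> CancerGene:
        return self._genes[symbol]

    def symbols(self) -> list[str]:
        return list(self._genes)

    def with_role(self, role: str) -> list[CancerGene]:
        return [g for g in self if g.role == role]

    @property
    def domain_universe(self) -> frozenset[str]:
        """All distinct accessions attached to any gene in the catalogue."""
        return frozenset(acc for g in self for acc in g.domain_accs)


@dataclass(frozen=True)
class DomainRoleProfile:
    """Per-domain TSG/OCG association counts, dual-role ratio and category."""

    domain_acc: str
    tsg_gene_count: int
    ocg_gene_count: int
    ratio: Optional[float]
    category: str
    domain_name: str = ""

    def __post_init__(self) -> None:
        if self.tsg_gene_count < 0 or self.ocg_gene_count < 0:
            raise ValidationError(f"{self.domain_acc}: negative gene count")

    @property
    def ratio_display(self) -> str:
        """Table rendering: 6 decimals, trailing zeros trimmed; undefined -> 'Not available'."""
        if self.ratio is None:
            return NOT_AVAILABLE
        text = f"{self.ratio:.6f}".rstrip("0").rstrip(".")
        return text or "0"


def dual_role_ratio(tsg_gene_count: int, ocg_gene_count: int) -> Optional[float]:
    """#TSGs / (#TSGs + #OCGs); ``None`` (not 0) when no gene of either role."""
    if tsg_gene_count < 0 or ocg_gene_count < 0:
        raise ValidationError("gene counts must be non-negative")
    total = tsg_gene_count + ocg_gene_count
    if total == 0:
        return None
    return tsg_gene_count / total


def categorize(tsg_gene_count: int, ocg_gene_count: int) -> str:
    if tsg_gene_count > 0 and ocg_gene_count == 0:
        return TSG_SPECIFIC
    if ocg_gene_count > 0 and tsg_gene_count == 0:
        return OCG_SPECIFIC
    if tsg_gene_count > 0 and ocg_gene_count > 0:
        return DUAL_ROLE
    return UNKNOWN


def merge_cancer_genes(
    tsg_symbols: Iterable[str],
    ocg_symbols: Iterable[str],
) -> CancerCatalog:
    """Merge TSG and OCG symbol lists into a non-redundant role-labelled catalogue.

    Symbols present in both lists become ``DUAL``.  Within-list duplicates are
    collapsed with a warning; matching is exact and case-sensitive.
    """
    tsg_list = list(tsg_symbols)
    ocg_list = list(ocg_symbols)
    if not tsg_list or not ocg_list:
        raise ValidationError("both gene lists must be non-empty")
    for name, lst in (("TSG", tsg_list), ("OCG", ocg_list)):
        if any(not isinstance(s, str) or not s for s in lst):
            raise ValidationError(f"{name} list contains an empty or non-string symbol")
        if len(set(lst)) != len(lst):
            logger.warning("%s list: %d duplicate symbols collapsed", name, len(lst) - len(set(lst)))
    tsg, ocg = set(tsg_list), set(ocg_list)
    genes = []
    for sym in tsg | ocg:
        role = DUAL if sym in tsg and sym in ocg else (TSG if sym in tsg else OCG)
        genes.append(CancerGene(sym, role))
    return CancerCatalog(genes)


def attach_domains(
    catalog: CancerCatalog,
    gene2domain: Mapping[str, Iterable[str]],
) -> tuple[CancerCatalog, tuple[int, int]]:
    """Attach domain accessions to catalogue genes (case-sensitive symbol match).

    Returns the updated catalogue and a coverage summary
    ``(n_genes_annotated, n_genes_total)``.  Mapping keys that match no
    catalogue symbol are logged, never fatal.
    """
    unmatched = [k for k in gene2domain if k not in catalog]
    if unmatched:
        logger.info("gene2domain: %d keys match no catalogue symbol (e.g. %s)",
                    len(unmatched), unmatched[:3])
    annotated = 0
    genes = []
    for g in catalog:
        accs = frozenset(gene2domain.get(g.gene_symbol, ()))
        if accs:
            annotated += 1
        genes.append(replace(g, domain_accs=accs))
    return CancerCatalog(genes), (annotated, len(catalog))


def classify_domain_roles(
    catalog: CancerCatalog,
    dual_counts_both: bool = True,
    domain_names: Optional[Mapping[str, str]] = None,
) -> dict[str, DomainRoleProfile]:
    """Classify every domain in the catalogue's annotation universe.

    With ``dual_counts_both`` (default), a DUAL gene increments both the TSG
    and the OCG tally of each of its domains; otherwise DUAL genes are
    excluded from both tallies.
    """
    names = domain_names or {}
    tsg_counts: dict[str, int] = {}
    ocg_counts: dict[str, int] = {}
    for acc in catalog.domain_universe:
        tsg_counts[acc] = 0
        ocg_counts[acc] = 0
    for g in catalog:
        for acc in g.domain_accs:
            if g.role == TSG:
                tsg_counts[acc] += 1
            elif g.role == OCG:
                ocg_counts[acc] += 1
            elif dual_counts_both:
                tsg_counts[acc] += 1
                ocg_counts[acc] += 1
    return {
        acc: DomainRoleProfile(
            domain_acc=acc,
            tsg_gene_count=tsg_counts[acc],
            ocg_gene_count=ocg_counts[acc],
            ratio=dual_role_ratio(tsg_counts[acc], ocg_counts[acc]),
            category=categorize(tsg_counts[acc], ocg_counts[acc]),
            domain_name=names.get(acc, ""),
        )
        for acc in sorted(tsg_counts)
    }


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_gene_list(path: str | Path) -> list[str]:
    """One symbol per line, or 2-column TSV (symbol, annotation); '#' comments."""
    symbols = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            symbols.append(line.split("\t")[0].strip())
    return symbols


def read_gene2domain(path: str | Path) -> dict[str, set[str]]:
    """2-column TSV (gene_symbol, accession), multiple rows per gene."""
    mapping: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValidationError(f"{path}:{lineno}: expected 2 columns (symbol, accession)")
            mapping.setdefault(fields[0], set()).add(strip_version(fields[1]))
    return mapping


def write_domain_role_profiles(
    profiles: Mapping[str, DomainRoleProfile], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("# domain_acc\tdomain_name\ttsg_gene_count\tocg_gene_count\tratio\tcategory\n")
        for acc in sorted(profiles):
            p = profiles[acc]
            fh.write(
                f"{p.domain_acc}\t{p.domain_name}\t{p.tsg_gene_count}\t"
                f"{p.ocg_gene_count}\t{p.ratio_display}\t{p.category}\n"
            )
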