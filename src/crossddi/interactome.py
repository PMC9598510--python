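"""Bipartite putative interactome between foreign proteins and human cancer genes.

A foreign protein p and a cancer gene g are predicted to interact when some
domain a annotated on p and some domain b annotated on g form an unordered
pair present in the DDI table.  An *interaction* is a distinct (protein, gene)
pair; the domain pairs supporting it are carried along, and their total
multiplicity is reported separately as ``n_domain_links`` because published
interaction totals may follow either convention.

Output ordering is a pure function of the data: interactions sort by
(species, protein, gene), supporting pairs lexicographically, so repeated runs
are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from crossddi.cancer_catalog import DUAL, OCG, TSG, CancerCatalog
from crossddi.core_io import DDITable, DomainAnnotation, ProteinRecord, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PutativeInteraction:
    """One predicted (foreign protein, cancer gene) link.

    ``supporting_pairs`` holds (foreign domain, human domain) pairs, each of
    which — unordered — occurs in the DDI table.  A DDI self-pair (a, a)
    yields the directed pair (a, a).
    """

    species_id: str
    protein_id: str
    gene_symbol: str
    supporting_pairs: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.supporting_pairs:
            raise ValidationError(
                f"{self.protein_id}-{self.gene_symbol}: interaction without supporting pairs"
            )


@dataclass(frozen=True)
class InteractomeSummary:
    species_id: str
    n_proteins_total: int
    n_proteins_with_domains: int
    n_interacting_proteins: int
    n_cancer_partners: int
    n_interactions: int
    n_domain_links: int
    partner_counts_by_role: Mapping[str, int]  # role -> #proteins with >=1 partner of that role

    def __post_init__(self) -> None:
        if not (
            self.n_interacting_proteins
            <= self.n_proteins_with_domains
            <= self.n_proteins_total
        ):
            raise ValidationError(
                f"{self.species_id}: protein counts violate "
                "interacting <= annotated <= total"
            )
        if self.n_interactions > self.n_domain_links:
            raise ValidationError(f"{self.species_id}: more interactions than domain links")
        for role, count in self.partner_counts_by_role.items():
            if count > self.n_interacting_proteins:
                raise ValidationError(
                    f"{self.species_id}: role group {role} exceeds interacting proteins"
                )


def build_interactome(
    annotations: Iterable[DomainAnnotation],
    catalog: CancerCatalog,
    ddi: DDITable,
    species_id: str = "unknown",
) -> list[PutativeInteraction]:
    """Predict all (protein, gene) pairs joined by at least one DDI pair.

    Genes with no attached domains never interact.  An empty DDI table yields
    an empty interactome with a warning.
    """
    if len(ddi) == 0:
        logger.warning("%s: empty DDI table, no interactions possible", species_id)
        return []

    protein_domains: dict[str, set[str]] = {}
    for ann in annotations:
        protein_domains.setdefault(ann.protein_id, set()).add(ann.domain_acc)

    # human domain -> genes carrying it
    genes_by_domain: dict[str, set[str]] = {}
    for gene in catalog:
        for acc in gene.domain_accs:
            genes_by_domain.setdefault(acc, set()).add(gene.gene_symbol)

    support: dict[tuple[str, str], set[tuple[str, str]]] = {}
    for pid in sorted(protein_domains):
        for a in protein_domains[pid]:
            for b in ddi.partners_of(a):
                for gene_symbol in genes_by_domain.get(b, ()):
                    support.setdefault((pid, gene_symbol), set()).add((a, b))

    return [
        PutativeInteraction(species_id, pid, gene, frozenset(pairs))
        for (pid, gene), pairs in sorted(support.items())
    ]


def summarize_interactome(
    interactome: Sequence[PutativeInteraction],
    proteome: Mapping[str, ProteinRecord],
    catalog: CancerCatalog,
    annotations: Iterable[DomainAnnotation] = (),
    species_id: str | None = None,
) -> InteractomeSummary:
    """Per-species interaction statistics.

    ``partner_counts_by_role`` counts a protein once per role group in which
    it has at least one partner; a protein partnering a TSG, an OCG and a
    dual-role gene contributes to all three groups.
    """
    if species_id is None:
        species_id = interactome[0].species_id if interactome else (
            next(iter(proteome.values())).species_id if proteome else "unknown"
        )
    annotated = {a.protein_id for a in annotations}
    interacting = {i.protein_id for i in interactome}
    partners = {i.gene_symbol for i in interactome}
    by_role: dict[str, set[str]] = {TSG: set(), OCG: set(), DUAL: set()}
    for i in interactome:
        by_role[catalog[i.gene_symbol].role].add(i.protein_id)
    return InteractomeSummary(
        species_id=species_id,
        n_proteins_total=len(proteome),
        n_proteins_with_domains=len(annotated) if annotated else len(proteome),
        n_interacting_proteins=len(interacting),
        n_cancer_partners=len(partners),
        n_interactions=len(interactome),
        n_domain_links=sum(len(i.supporting_pairs) for i in interactome),
        partner_counts_by_role={r: len(p) for r, p in by_role.items()},
    )


def rank_domains_by_interactions(
    interactome: Sequence[PutativeInteraction],
    profiles: Mapping[str, "object"],
    k: int,
) -> list[tuple[str, int, str, object]]:
    """Top-k foreign domains by the number of interactions they support.

    A domain's count is the number of (protein, gene) pairs whose supporting
    pairs include that accession on the foreign side.  Ties break by accession
    ascending.  Returns (accession, count, category, ratio) tuples; domains
    absent from ``profiles`` get category ``UNKNOWN`` and ratio ``None``.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    counts: dict[str, int] = {}
    for i in interactome:
        for foreign_acc in {a for a, _ in i.supporting_pairs}:
            counts[foreign_acc] = counts.get(foreign_acc, 0) + 1
    ranked = sorted(counts.items(), key=lambda item: (-item[1], item[0]))[:k]
    out = []
    for acc, n in ranked:
        prof = profiles.get(acc)
        category = getattr(prof, "category", "UNKNOWN")
        ratio = getattr(prof, "ratio", None)
        out.append((acc, n, category, ratio))
    return out


def filter_tsg_hubs(
    interactome: Sequence[PutativeInteraction],
    catalog: CancerCatalog,
    min_tsg_partners: int = 100,
    include_dual: bool = False,
) -> set[str]:
    """Proteins with >= ``min_tsg_partners`` distinct tumour-suppressor partners.

    The threshold is inclusive.  Dual-role partner genes count only when
    ``include_dual`` is set.
    """
    if min_tsg_partners < 1:
        raise ValidationError("min_tsg_partners must be >= 1")
    roles = {TSG} | ({DUAL} if include_dual else set())
    partners: dict[str, set[str]] = {}
    for i in interactome:
        if catalog[i.gene_symbol].role in roles:
            partners.setdefault(i.protein_id, set()).add(i.gene_symbol)
    return {pid for pid, genes in partners.items() if len(genes) >= min_tsg_partners}


def cross_species_overlaps(
    interactomes: Mapping[str, Sequence[PutativeInteraction]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise overlap matrices across species interactomes.

    Returns two symmetric integer DataFrames indexed by species id: shared
    cancer-partner gene counts and shared foreign interacting-domain counts.
    Diagonals are the per-species set sizes.
    """
    if len(interactomes) < 2:
        raise ValidationError("need at least 2 interactomes to compare")
    species = sorted(interactomes)
    gene_sets = {
        s: {i.gene_symbol for i in interactomes[s]} for s in species
    }
    domain_sets = {
        s: {a for i in interactomes[s] for a, _ in i.supporting_pairs} for s in species
    }
    genes = pd.DataFrame(
        [[len(gene_sets[r] & gene_sets[c]) for c in species] for r in species],
        index=species, columns=species, dtype=int,
    )
    domains = pd.DataFrame(
        [[len(domain_sets[r] & domain_sets[c]) for c in species] for r in species],
        index=species, columns=species, dtype=int,
    )
    return genes, domains


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_interactome(
    interactome: Sequence[PutativeInteraction],
    catalog: CancerCatalog,
    path: str | Path,
) -> None:
    with open(path, "w") as fh:
        fh.write("# species_id\tprotein_id\tgene_symbol\tgene_role\tsupporting_pairs\n")
        for i in sorted(interactome, key=lambda x: (x.species_id, x.protein_id, x.gene_symbol)):
            pairs = ";".join(f"{a}:{b}" for a, b in sorted(i.supporting_pairs))
            fh.write(
                f"{i.species_id}\t{i.protein_id}\t{i.gene_symbol}\t"
                f"{catalog[i.gene_symbol].role}\t{pairs}\n"
            )


def write_summaries(summaries: Sequence[InteractomeSummary], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "# species_id\tn_proteins_total\tn_proteins_with_domains\t"
            "n_interacting_proteins\tn_cancer_partners\tn_interactions\t"
            "n_domain_links\tn_vs_tsg\tn_vs_ocg\tn_vs_dual\n"
        )
        for s in summaries:
            fh.write(
                f"{s.species_id}\t{s.n_proteins_total}\t{s.n_proteins_with_domains}\t"
                f"{s.n_interacting_proteins}\t{s.n_cancer_partners}\t{s.n_interactions}\t"
                f"{s.n_domain_links}\t{s.partner_counts_by_role[TSG]}\t"
                f"{s.partner_counts_by_role[OCG]}\t{s.partner_counts_by_role[DUAL]}\n"
            )


def write_overlap_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="species_id")
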