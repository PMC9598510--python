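"""End-to-end convenience driver: load a dataset directory, run every stage.

Thin glue over the stage modules, used by the command-line interface and by
verification against synthetic ground truth.  The directory layout is the one
the synthetic generator emits: per-species ``<sp>.fasta`` +
``<sp>.annotations.tsv``, plus ``tsg_genes.tsv``, ``ocg_genes.tsv``,
``gene2domain.tsv``, ``ddi.tsv``, ``signalp.tsv`` and ``tmhmm.txt``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from crossddi import cancer_catalog as cc
from crossddi import core_io, interactome as itx, secretome
from crossddi.cancer_catalog import CancerCatalog, DomainRoleProfile
from crossddi.interactome import InteractomeSummary, PutativeInteraction


@dataclass
class PipelineResult:
    catalog: CancerCatalog
    profiles: Mapping[str, DomainRoleProfile]
    interactomes: Mapping[str, Sequence[PutativeInteraction]]
    summaries: Mapping[str, InteractomeSummary]
    hub_ids: frozenset[str]
    secreted_hub_ids: frozenset[str]

    @property
    def interaction_triples(self) -> frozenset[tuple[str, str, str]]:
        return frozenset(
            (i.species_id, i.protein_id, i.gene_symbol)
            for inter in self.interactomes.values()
            for i in inter
        )


def run_pipeline(
    dataset_dir: str | Path,
    accepted_confidence: frozenset[str] = frozenset({"HC"}),
    min_tsg_partners: int = 100,
    include_dual: bool = False,
    nterm_exempt_len: int = 0,
) -> PipelineResult:
    """Run catalogue construction, interactome inference, hub filtering and
    secretome intersection on one dataset directory."""
    dataset_dir = Path(dataset_dir)

    tsg = cc.read_gene_list(dataset_dir / "tsg_genes.tsv")
    ocg = cc.read_gene_list(dataset_dir / "ocg_genes.tsv")
    catalog = cc.merge_cancer_genes(tsg, ocg)
    gene2domain = cc.read_gene2domain(dataset_dir / "gene2domain.tsv")
    catalog, _coverage = cc.attach_domains(catalog, gene2domain)
    profiles = cc.classify_domain_roles(catalog)

    ddi = core_io.read_ddi_table(dataset_dir / "ddi.tsv", accepted_confidence)

    interactomes: dict[str, list[PutativeInteraction]] = {}
    summaries: dict[str, InteractomeSummary] = {}
    all_hubs: set[str] = set()
    for fasta in sorted(dataset_dir.glob("*.fasta")):
        species_id = fasta.stem
        proteome = core_io.read_proteome(fasta, species_id)
        annotations = core_io.read_domain_annotations(
            dataset_dir / f"{species_id}.annotations.tsv", dialect="tsv"
        )
        inter = itx.build_interactome(annotations, catalog, ddi, species_id)
        interactomes[species_id] = inter
        summaries[species_id] = itx.summarize_interactome(
            inter, proteome, catalog, annotations, species_id
        )
        all_hubs |= itx.filter_tsg_hubs(inter, catalog, min_tsg_partners, include_dual)

    evidence = core_io.read_secretion_tables(
        dataset_dir / "signalp.tsv", dataset_dir / "tmhmm.txt"
    )
    calls = secretome.call_secreted(evidence, nterm_exempt_len)
    secreted_hubs = secretome.secreted_tsg_hubs(calls, all_hubs)

    return PipelineResult(
        catalog=catalog,
        profiles=profiles,
        interactomes=interactomes,
        summaries=summaries,
        hub_ids=frozenset(all_hubs),
        secreted_hub_ids=frozenset(secreted_hubs),
    )
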