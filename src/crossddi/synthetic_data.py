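"""Synthetic multi-species benchmark datasets with planted ground truth.

The generator emulates the statistical shape of the pipeline's real inputs —
several foreign proteomes sharing a domain vocabulary, role-labelled cancer
gene lists with a controlled dual-role overlap, a confidence-tiered DDI
table, and signal-peptide/transmembrane prediction tables — and writes them
in exactly the formats :mod:`crossddi.core_io` reads.  A known ground truth
(all expected interactions, every domain's role category, and the planted
secreted TSG hubs) is computed by an independent brute-force procedure over
the emitted structures, so every pipeline stage can be verified exactly.

Hub planting is constructive: each planted hub protein carries a dedicated
domain that is deliberately wired, with high-confidence DDI edges, to enough
tumour-suppressor gene domains to guarantee the configured number of distinct
TSG partners.  Unsatisfiable configurations are rejected before any file is
written.  Amino-acid content is random (only lengths matter downstream).

One integer seed drives everything; per-component generators are derived
deterministically from it, so the same seed always yields byte-identical
files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import yaml

from crossddi.core_io import ValidationError, canonical_pair
from crossddi.cancer_catalog import categorize

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: confidence labels understood by the generator; truth uses HC edges only
CONFIDENCE_LABELS = ("HC", "MC", "LC", "NA")


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the generator; defaults give a dataset that runs in seconds."""

    seed: int = 0
    n_species: int = 5
    proteins_per_species: int = 200
    domain_vocab_size: int = 150
    domains_per_protein: tuple[int, int] = (0, 5)
    domains_per_gene: tuple[int, int] = (1, 3)
    protein_length_range: tuple[int, int] = (80, 400)
    n_tsg: int = 120
    n_ocg: int = 80
    n_dual_overlap: int = 15
    ddi_density: float = 0.02
    ddi_confidence_mix: tuple[float, ...] = (0.6, 0.25, 0.15, 0.0)  # HC, MC, LC, NA
    frac_signal_peptide: float = 0.15
    frac_tm: float = 0.25
    n_planted_secreted_hubs: int = 5
    hub_tsg_partner_target: int = 100

    def validate(self) -> None:
        if self.n_dual_overlap > min(self.n_tsg, self.n_ocg):
            raise ValidationError("n_dual_overlap exceeds a source list size")
        if not 0.0 <= self.ddi_density <= 1.0:
            raise ValidationError("ddi_density must lie in [0, 1]")
        for frac in (self.frac_signal_peptide, self.frac_tm):
            if not 0.0 <= frac <= 1.0:
                raise ValidationError("secretion fractions must lie in [0, 1]")
        if len(self.ddi_confidence_mix) != len(CONFIDENCE_LABELS):
            raise ValidationError("ddi_confidence_mix must give one proportion per label")
        if any(p < 0 for p in self.ddi_confidence_mix) or not np.isclose(
            sum(self.ddi_confidence_mix), 1.0
        ):
            raise ValidationError("ddi_confidence_mix proportions must be >=0 and sum to 1")
        n_tsg_only = self.n_tsg - self.n_dual_overlap
        if self.n_planted_secreted_hubs > 0 and self.hub_tsg_partner_target > n_tsg_only:
            raise ValidationError(
                f"hub target {self.hub_tsg_partner_target} exceeds the "
                f"{n_tsg_only} TSG-specific genes available"
            )
        if self.n_planted_secreted_hubs > self.n_species * self.proteins_per_species:
            raise ValidationError("more planted hubs than proteins")
        if self.domain_vocab_size < self.n_planted_secreted_hubs + 10:
            raise ValidationError("domain vocabulary too small for hub reservation")
        lo, hi = self.domains_per_protein
        if not 0 <= lo <= hi:
            raise ValidationError("bad domains_per_protein range")
        glo, ghi = self.domains_per_gene
        if not 1 <= glo <= ghi:
            raise ValidationError("bad domains_per_gene range")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("domains_per_protein", "domains_per_gene",
                    "protein_length_range", "ddi_confidence_mix"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass(frozen=True)
class GroundTruth:
    """What the pipeline must recover, stage by stage."""

    expected_interactions: frozenset[tuple[str, str, str]]  # (species, protein, gene)
    expected_domain_categories: Mapping[str, str]
    expected_hub_ids: frozenset[str]
    expected_secreted_hub_ids: frozenset[str]


@dataclass(frozen=True)
class VerificationReport:
    interactions_match: bool
    categories_match: bool
    secreted_hubs_match: bool
    interaction_diff: frozenset[tuple[str, str, str]]
    category_diff: frozenset[str]
    secreted_hub_diff: frozenset[str]

    @property
    def all_match(self) -> bool:
        return self.interactions_match and self.categories_match and self.secreted_hubs_match


def brute_force_interactions(
    protein_domains: Mapping[str, Iterable[str]],
    gene_domains: Mapping[str, Iterable[str]],
    ddi_pairs: Iterable[tuple[str, str]],
    species_of: Mapping[str, str],
) -> frozenset[tuple[str, str, str]]:
    """Reference enumeration: every (species, protein, gene) joined by a DDI pair."""
    pairs = {canonical_pair(a, b) for a, b in ddi_pairs}
    hits = set()
    for pid, pdoms in protein_domains.items():
        for gene, gdoms in gene_domains.items():
            if any(canonical_pair(a, b) in pairs for a in pdoms for b in gdoms):
                hits.add((species_of[pid], pid, gene))
    return frozenset(hits)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, stream])


def generate_dataset(config: SyntheticConfig, out_dir: str | Path) -> GroundTruth:
    """Write a complete synthetic dataset plus its ground truth under ``out_dir``.

    Emits per species a FASTA proteome and an annotation TSV, plus TSG/OCG
    gene lists, a gene->domain TSV, a DDI TSV with confidence labels, and
    SignalP-5-like / TMHMM-2-like tables.  Ground truth is serialised under
    ``out_dir/ground_truth/``.
    """
    config.validate()
    out_dir = Path(out_dir)

    # --- vocabularies and identities -------------------------------------
    vocab = [f"PF9{i:04d}" for i in range(config.domain_vocab_size)]
    hub_domains = vocab[-config.n_planted_secreted_hubs:] if config.n_planted_secreted_hubs else []
    pool = vocab[: config.domain_vocab_size - config.n_planted_secreted_hubs]
    domain_name = {acc: f"D{acc[3:]}" for acc in vocab}

    n_dual = config.n_dual_overlap
    dual_syms = [f"DUALGENE{i:04d}" for i in range(n_dual)]
    tsg_only = [f"TSGENE{i:04d}" for i in range(config.n_tsg - n_dual)]
    ocg_only = [f"ONCOGENE{i:04d}" for i in range(config.n_ocg - n_dual)]
    tsg_list = tsg_only + dual_syms
    ocg_list = ocg_only + dual_syms

    # --- gene -> domain assignments --------------------------------------
    rng = _rng(config.seed, 1)
    gene_domains: dict[str, set[str]] = {}
    glo, ghi = config.domains_per_gene
    for sym in tsg_only + ocg_only + dual_syms:
        k = int(rng.integers(glo, ghi + 1))
        gene_domains[sym] = set(rng.choice(pool, size=min(k, len(pool)), replace=False))

    # --- species proteomes and annotations -------------------------------
    species_ids = [f"sp{i + 1}" for i in range(config.n_species)]
    rng = _rng(config.seed, 2)
    plo, phi = config.domains_per_protein
    llo, lhi = config.protein_length_range
    sequences: dict[str, str] = {}
    protein_domains: dict[str, set[str]] = {}
    species_of: dict[str, str] = {}
    proteins_by_species: dict[str, list[str]] = {s: [] for s in species_ids}
    for sp in species_ids:
        for j in range(config.proteins_per_species):
            pid = f"{sp}_p{j:05d}"
            length = int(rng.integers(llo, lhi + 1))
            sequences[pid] = "".join(rng.choice(AMINO_ACIDS, size=length))
            k = int(rng.integers(plo, phi + 1))
            protein_domains[pid] = set(rng.choice(pool, size=k, replace=False)) if k else set()
            species_of[pid] = sp
            proteins_by_species[sp].append(pid)

    # --- planted hubs: dedicated domain + deliberate HC wiring ------------
    hub_ids: list[str] = []
    wired_edges: set[tuple[str, str]] = set()
    for h in range(config.n_planted_secreted_hubs):
        sp = species_ids[h % config.n_species]
        pid = proteins_by_species[sp][h // config.n_species]
        hub_ids.append(pid)
        hub_dom = hub_domains[h]
        protein_domains[pid].add(hub_dom)
        covered: set[str] = set()
        for gene in tsg_only:
            if len(covered) >= config.hub_tsg_partner_target:
                break
            if gene in covered:
                continue
            target_dom = min(gene_domains[gene])
            wired_edges.add(canonical_pair(hub_dom, target_dom))
            covered.update(
                g for g in tsg_only if target_dom in gene_domains[g]
            )

    # --- random DDI entries over the general pool -------------------------
    rng = _rng(config.seed, 3)
    n_possible = len(pool) * (len(pool) - 1) // 2
    n_random = int(round(config.ddi_density * n_possible))
    random_pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    while len(random_pairs) < n_random:
        i, j = rng.integers(0, len(pool), size=2)
        if i == j:
            continue
        pair = canonical_pair(pool[int(i)], pool[int(j)])
        if pair not in seen:
            seen.add(pair)
            random_pairs.append(pair)
    labels = rng.choice(CONFIDENCE_LABELS, size=len(random_pairs),
                        p=list(config.ddi_confidence_mix))
    ddi_rows: list[tuple[str, str, str]] = [(a, b, "HC") for a, b in sorted(wired_edges)]
    ddi_rows += [(a, b, str(lab)) for (a, b), lab in zip(random_pairs, labels)]

    hc_pairs = [(a, b) for a, b, lab in ddi_rows if lab == "HC"]

    # --- ground truth by independent brute force --------------------------
    truth_interactions = brute_force_interactions(
        protein_domains, gene_domains, hc_pairs, species_of
    )
    tsg_roles = set(tsg_only)
    tsg_partners: dict[str, set[str]] = {}
    for _, pid, gene in truth_interactions:
        if gene in tsg_roles:
            tsg_partners.setdefault(pid, set()).add(gene)
    true_hubs = frozenset(
        pid for pid, genes in tsg_partners.items()
        if len(genes) >= config.hub_tsg_partner_target
    )
    missing = set(hub_ids) - true_hubs
    if missing:  # defensive: wiring guarantees this cannot happen
        raise ValidationError(f"planted hubs failed to reach target: {sorted(missing)}")

    ocg_only_set, tsg_only_set = set(ocg_only), set(tsg_only)
    categories = {
        acc: categorize(
            sum(1 for g in gene_domains if acc in gene_domains[g] and g not in ocg_only_set),
            sum(1 for g in gene_domains if acc in gene_domains[g] and g not in tsg_only_set),
        )
        for acc in sorted({a for doms in gene_domains.values() for a in doms})
    }

    # --- secretion evidence ----------------------------------------------
    # Planted hubs are secreted by construction.  Any *accidental* hub is
    # forced non-secreted so "planted secreted hubs" is an exact set.
    rng = _rng(config.seed, 4)
    sp_call: dict[str, bool] = {}
    tm_spans: dict[str, list[tuple[int, int]]] = {}
    for pid in sorted(sequences):
        if pid in hub_ids:
            sp_call[pid] = True
            tm_spans[pid] = []
            continue
        secreted_ok = pid not in true_hubs
        sp_call[pid] = secreted_ok and bool(rng.random() < config.frac_signal_peptide)
        spans: list[tuple[int, int]] = []
        if rng.random() < config.frac_tm:
            length = len(sequences[pid])
            n_helix = int(rng.integers(1, 4))
            start = 10
            for _ in range(n_helix):
                end = start + 20
                if end >= length:
                    break
                spans.append((start, end))
                start = end + 25
        tm_spans[pid] = spans
    secreted_hub_ids = frozenset(hub_ids)

    truth = GroundTruth(
        expected_interactions=truth_interactions,
        expected_domain_categories=categories,
        expected_hub_ids=true_hubs,
        expected_secreted_hub_ids=secreted_hub_ids,
    )

    # --- write everything -------------------------------------------------
    out_dir.mkdir(parents=True, exist_ok=True)
    for sp in species_ids:
        with open(out_dir / f"{sp}.fasta", "w") as fh:
            for pid in proteins_by_species[sp]:
                fh.write(f">{pid}\n")
                seq = sequences[pid]
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
        with open(out_dir / f"{sp}.annotations.tsv", "w") as fh:
            fh.write("# protein_id\tdomain_acc\tdomain_name\n")
            for pid in proteins_by_species[sp]:
                for acc in sorted(protein_domains[pid]):
                    fh.write(f"{pid}\t{acc}\t{domain_name[acc]}\n")

    with open(out_dir / "tsg_genes.tsv", "w") as fh:
        fh.writelines(f"{s}\n" for s in tsg_list)
    with open(out_dir / "ocg_genes.tsv", "w") as fh:
        fh.writelines(f"{s}\n" for s in ocg_list)
    with open(out_dir / "gene2domain.tsv", "w") as fh:
        for sym in sorted(gene_domains):
            for acc in sorted(gene_domains[sym]):
                fh.write(f"{sym}\t{acc}\n")
    with open(out_dir / "ddi.tsv", "w") as fh:
        fh.write("# domain_a\tdomain_b\tconfidence\n")
        for a, b, lab in ddi_rows:
            fh.write(f"{a}\t{b}\t{lab}\n")
    with open(out_dir / "signalp.tsv", "w") as fh:
        fh.write("# ID\tPrediction\tSP(Sec/SPI)\tOTHER\tCS Position\n")
        for pid in sorted(sequences):
            if sp_call[pid]:
                fh.write(f"{pid}\tSP(Sec/SPI)\t0.9800\t0.0200\tCS pos: 22-23\n")
            else:
                fh.write(f"{pid}\tOTHER\t0.0100\t0.9900\n")
    with open(out_dir / "tmhmm.txt", "w") as fh:
        for pid in sorted(sequences):
            spans = tm_spans[pid]
            topo = "o" + "".join(f"{s}-{e}{'io'[i % 2]}" for i, (s, e) in enumerate(spans))
            fh.write(
                f"{pid}\tlen={len(sequences[pid])}\tExpAA={21.5 * len(spans):.2f}\t"
                f"First60=0.00\tPredHel={len(spans)}\tTopology={topo}\n"
            )

    truth_dir = out_dir / "ground_truth"
    truth_dir.mkdir(exist_ok=True)
    with open(truth_dir / "interactions.tsv", "w") as fh:
        fh.write("# species_id\tprotein_id\tgene_symbol\n")
        for sp, pid, gene in sorted(truth_interactions):
            fh.write(f"{sp}\t{pid}\t{gene}\n")
    with open(truth_dir / "domain_categories.tsv", "w") as fh:
        fh.write("# domain_acc\tcategory\n")
        for acc in sorted(categories):
            fh.write(f"{acc}\t{categories[acc]}\n")
    with open(truth_dir / "hubs.tsv", "w") as fh:
        fh.write("# protein_id\n")
        fh.writelines(f"{pid}\n" for pid in sorted(true_hubs))
    with open(truth_dir / "secreted_hubs.tsv", "w") as fh:
        fh.write("# protein_id\n")
        fh.writelines(f"{pid}\n" for pid in sorted(secreted_hub_ids))
    with open(out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)

    return truth


def load_ground_truth(dataset_dir: str | Path) -> GroundTruth:
    """Re-read the serialised ground truth written next to a dataset."""
    truth_dir = Path(dataset_dir) / "ground_truth"

    def rows(name: str) -> list[list[str]]:
        with open(truth_dir / name) as fh:
            return [
                line.rstrip("\n").split("\t")
                for line in fh
                if line.strip() and not line.startswith("#")
            ]

    return GroundTruth(
        expected_interactions=frozenset(tuple(r) for r in rows("interactions.tsv")),
        expected_domain_categories={r[0]: r[1] for r in rows("domain_categories.tsv")},
        expected_hub_ids=frozenset(r[0] for r in rows("hubs.tsv")),
        expected_secreted_hub_ids=frozenset(r[0] for r in rows("secreted_hubs.tsv")),
    )


def verify_against_truth(
    interactions: Iterable[tuple[str, str, str]],
    domain_categories: Mapping[str, str],
    secreted_hub_ids: Iterable[str],
    truth: GroundTruth,
) -> VerificationReport:
    """Exact set comparison of pipeline outputs against ground truth.

    Category comparison is restricted to the truth's domain universe (the
    pipeline may legitimately classify extra domains never seen on a gene).
    """
    got_inter = frozenset(interactions)
    inter_diff = got_inter ^ truth.expected_interactions
    cat_diff = frozenset(
        acc
        for acc, cat in truth.expected_domain_categories.items()
        if domain_categories.get(acc) != cat
    )
    got_hubs = frozenset(secreted_hub_ids)
    hub_diff = got_hubs ^ truth.expected_secreted_hub_ids
    return VerificationReport(
        interactions_match=not inter_diff,
        categories_match=not cat_diff,
        secreted_hubs_match=not hub_diff,
        interaction_diff=inter_diff,
        category_diff=cat_diff,
        secreted_hub_diff=hub_diff,
    )
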