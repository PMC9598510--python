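"""Typed records and readers/writers for the external formats the pipeline consumes.

Readers cover protein FASTA, HMMER3 per-domain tabular output (``domtblout``),
a plain 3/6-column annotation TSV, DOMINE-style DDI tables, SignalP 5 short
tabular output and TMHMM 2 short-format output.  All writers emit TSV with a
single ``#``-commented header line so that every loaded table round-trips.

Coordinates are 1-based inclusive throughout (HMMER/TMHMM convention).
Pfam accession version suffixes (``PF00069.25`` -> ``PF00069``) are stripped
on load so that annotation and DDI vocabularies join on bare accessions.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

PFAM_ACC_RE = re.compile(r"^PF\d{5}$")

#: default independent E-value cutoff for domtblout rows
DEFAULT_EVALUE_MAX = 1e-5


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


class ValidationError(ValueError):
    """Parsed content violates a semantic invariant (duplicate ids, bad counts...)."""


def strip_version(acc: str) -> str:
    """Drop a trailing ``.NN`` version from a Pfam-style accession."""
    head, sep, tail = acc.partition(".")
    return head if sep and tail.isdigit() else acc


def _check_acc(acc: str, where: str) -> None:
    if not PFAM_ACC_RE.match(acc):
        raise ValidationError(
            f"{where}: accession {acc!r} does not match the Pfam pattern PF+5 digits "
            "(pass pfam_pattern=False for synthetic vocabularies)"
        )


# ---------------------------------------------------------------------------
# record types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinRecord:
    """One protein of one species; sequence is optional (annotation-only inputs)."""

    protein_id: str
    species_id: str
    length: int
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ValidationError(f"protein {self.protein_id}: negative length")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValidationError(
                f"protein {self.protein_id}: length {self.length} != "
                f"sequence length {len(self.sequence)}"
            )


@dataclass(frozen=True)
class DomainAnnotation:
    """A domain-family assignment on a protein.

    ``envelope_start``/``envelope_end`` are 1-based inclusive residue
    coordinates of the domain envelope, when the source format provides them.
    """

    protein_id: str
    domain_acc: str
    domain_name: str = ""
    evalue: Optional[float] = None
    envelope_start: Optional[int] = None
    envelope_end: Optional[int] = None

    def __post_init__(self) -> None:
        if self.evalue is not None and self.evalue < 0:
            raise ValidationError(f"{self.protein_id}/{self.domain_acc}: negative E-value")
        if (
            self.envelope_start is not None
            and self.envelope_end is not None
            and self.envelope_start > self.envelope_end
        ):
            raise ValidationError(
                f"{self.protein_id}/{self.domain_acc}: envelope start "
                f"{self.envelope_start} > end {self.envelope_end}"
            )


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Unordered domain pair in canonical (lexicographic) order."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class DDIEntry:
    """One unordered domain-domain interaction with a confidence label."""

    domain_a: str
    domain_b: str
    confidence: str = "NA"

    def __post_init__(self) -> None:
        if self.domain_a > self.domain_b:
            raise ValidationError(
                f"DDIEntry ({self.domain_a}, {self.domain_b}) not in canonical order; "
                "use DDIEntry.make()"
            )

    @classmethod
    def make(cls, domain_a: str, domain_b: str, confidence: str = "NA") -> "DDIEntry":
        a, b = canonical_pair(domain_a, domain_b)
        return cls(a, b, confidence)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.domain_a, self.domain_b)


class DDITable:
    """A de-duplicated set of unordered domain pairs with an adjacency view.

    Self-pairs (a domain interacting with itself) are permitted and stored
    once.  ``n_dropped_confidence`` records how many input rows were discarded
    by the confidence filter at load time.
    """

    def __init__(self, entries: Iterable[DDIEntry], n_dropped_confidence: int = 0):
        by_pair: dict[tuple[str, str], DDIEntry] = {}
        for e in entries:
            by_pair.setdefault(e.pair, e)
        self._entries = dict(sorted(by_pair.items()))
        self.n_dropped_confidence = n_dropped_confidence
        self._adjacency: dict[str, set[str]] = {}
        for a, b in self._entries:
            self._adjacency.setdefault(a, set()).add(b)
            self._adjacency.setdefault(b, set()).add(a)

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries.values())

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return canonical_pair(*pair) in self._entries

    def __eq__(self, other) -> bool:
        return isinstance(other, DDITable) and self._entries.keys() == other._entries.keys()

    def partners_of(self, domain: str) -> frozenset[str]:
        """All domains the given domain interacts with (itself included for self-pairs)."""
        return frozenset(self._adjacency.get(domain, ()))

    @property
    def domains(self) -> frozenset[str]:
        return frozenset(self._adjacency)

    @property
    def pairs(self) -> frozenset[tuple[str, str]]:
        return frozenset(self._entries)


@dataclass(frozen=True)
class SecretionEvidence:
    """Merged signal-peptide and transmembrane evidence for one protein."""

    protein_id: str
    sp_call: bool
    sp_probability: Optional[float] = None
    tm_helix_count: int = 0
    tm_helix_spans: Optional[tuple[tuple[int, int], ...]] = None

    def __post_init__(self) -> None:
        if self.tm_helix_count < 0:
            raise ValidationError(f"{self.protein_id}: negative TM helix count")
        if self.sp_probability is not None and not 0.0 <= self.sp_probability <= 1.0:
            raise ValidationError(f"{self.protein_id}: SP probability outside [0,1]")
        if self.tm_helix_spans is not None:
            if len(self.tm_helix_spans) != self.tm_helix_count:
                raise ValidationError(
                    f"{self.protein_id}: PredHel={self.tm_helix_count} but "
                    f"{len(self.tm_helix_spans)} topology spans"
                )
            for s, e in self.tm_helix_spans:
                if not 1 <= s <= e:
                    raise ValidationError(f"{self.protein_id}: bad TM span [{s},{e}]")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_proteome(path: str | Path, species_id: str) -> dict[str, ProteinRecord]:
    """Load a protein FASTA file as ``{protein_id: ProteinRecord}``.

    The identifier is the first whitespace-delimited token of the header.
    Duplicate identifiers are rejected; an empty file yields an empty mapping
    with a warning.
    """
    path = Path(path)
    records: dict[str, ProteinRecord] = {}
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:  # biopython signals malformed records this way
        raise FormatError(f"{path}: malformed FASTA: {exc}") from exc
    for rec in parsed:
        if rec.id in records:
            raise ValidationError(f"{path}: duplicate protein identifier {rec.id!r}")
        seq = str(rec.seq)
        records[rec.id] = ProteinRecord(rec.id, species_id, len(seq), seq)
    if not records:
        logger.warning("%s: no FASTA records found", path)
    return records


# domtblout column layout (whitespace-separated, 22 fixed columns + description):
# 0 target name, 3 query name, 4 query accession, 12 i-Evalue, 19-20 env from/to
_DOMTBL_MIN_COLS = 22


def _parse_domtbl_row(fields: Sequence[str], path: Path, lineno: int) -> DomainAnnotation:
    try:
        acc = strip_version(fields[4])
        return DomainAnnotation(
            protein_id=fields[0],
            domain_acc=acc,
            domain_name=fields[3],
            evalue=float(fields[12]),
            envelope_start=int(fields[19]),
            envelope_end=int(fields[20]),
        )
    except (IndexError, ValueError) as exc:
        raise FormatError(f"{path}:{lineno}: unparsable domtblout row: {exc}") from exc


def read_domain_annotations(
    path: str | Path,
    dialect: str = "tsv",
    evalue_max: float = DEFAULT_EVALUE_MAX,
    pfam_pattern: bool = True,
) -> list[DomainAnnotation]:
    """Load protein -> domain assignments.

    ``dialect="domtblout"`` parses HMMER3 per-domain tabular output and keeps
    rows with independent E-value <= ``evalue_max``.  ``dialect="tsv"`` loads a
    pre-thresholded table verbatim: 3 columns (protein_id, domain_acc,
    domain_name) or the 6-column form this module's writer emits.  Version
    suffixes on accessions are stripped in both dialects.
    """
    path = Path(path)
    if dialect not in ("domtblout", "tsv"):
        raise FormatError(f"unknown annotation dialect {dialect!r}")
    if dialect == "domtblout" and evalue_max <= 0:
        raise ValidationError("evalue_max must be positive")

    out: list[DomainAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if dialect == "domtblout":
                fields = line.split()
                if len(fields) < _DOMTBL_MIN_COLS:
                    raise FormatError(
                        f"{path}:{lineno}: expected >={_DOMTBL_MIN_COLS} domtblout "
                        f"columns, got {len(fields)}"
                    )
                ann = _parse_domtbl_row(fields, path, lineno)
                if ann.evalue is not None and ann.evalue > evalue_max:
                    continue
            else:
                fields = line.split("\t")
                if len(fields) < 3:
                    raise FormatError(
                        f"{path}:{lineno}: expected >=3 tab-separated columns"
                    )
                try:
                    ann = DomainAnnotation(
                        protein_id=fields[0],
                        domain_acc=strip_version(fields[1]),
                        domain_name=fields[2],
                        evalue=None if len(fields) < 4 or fields[3] == "." else float(fields[3]),
                        envelope_start=None if len(fields) < 6 or fields[4] == "." else int(fields[4]),
                        envelope_end=None if len(fields) < 6 or fields[5] == "." else int(fields[5]),
                    )
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: unparsable row: {exc}") from exc
            if pfam_pattern:
                _check_acc(ann.domain_acc, f"{path}:{lineno}")
            out.append(ann)
    if not out:
        logger.warning("%s: no annotations loaded", path)
    return out


def read_ddi_table(
    path: str | Path,
    accepted_confidence: Iterable[str],
    pfam_pattern: bool = True,
) -> DDITable:
    """Load a DOMINE-like TSV (domain_a, domain_b, confidence).

    Only rows whose confidence label is accepted are kept; pairs are
    canonicalised unordered and de-duplicated.  The number of rows dropped by
    the confidence filter is recorded on the returned table.
    """
    accepted = set(accepted_confidence)
    if not accepted:
        raise ValidationError("accepted_confidence must be non-empty")
    path = Path(path)
    entries: list[DDIEntry] = []
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns (a, b, confidence)")
            a, b = strip_version(fields[0]), strip_version(fields[1])
            if pfam_pattern:
                _check_acc(a, f"{path}:{lineno}")
                _check_acc(b, f"{path}:{lineno}")
            if fields[2] in accepted:
                entries.append(DDIEntry.make(a, b, fields[2]))
            else:
                dropped += 1
    return DDITable(entries, n_dropped_confidence=dropped)


_PREDHEL_RE = re.compile(r"PredHel=(\d+)")
_TOPO_RE = re.compile(r"Topology=(\S+)")
_SPAN_RE = re.compile(r"(\d+)-(\d+)")


def parse_topology(topology: str) -> tuple[tuple[int, int], ...]:
    """Parse a TMHMM short-format topology string into helix spans.

    ``"o10-32i50-70o"`` -> ``((10, 32), (50, 70))``; a bare ``"i"``/``"o"``
    (no helix) yields an empty tuple.
    """
    spans = tuple((int(s), int(e)) for s, e in _SPAN_RE.findall(topology))
    for s, e in spans:
        if s > e:
            raise FormatError(f"topology span {s}-{e} reversed in {topology!r}")
    return spans


def read_secretion_tables(
    signalp_path: str | Path,
    tmhmm_path: str | Path,
) -> dict[str, SecretionEvidence]:
    """Merge SignalP 5 short output and TMHMM 2 short output per protein.

    Outer join on protein id: a protein absent from the SignalP table gets
    ``sp_call=False``; one absent from the TMHMM table gets zero helices.
    """
    sp: dict[str, tuple[bool, Optional[float]]] = {}
    with open(signalp_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise FormatError(f"{signalp_path}:{lineno}: expected id + prediction")
            prob = None
            if len(fields) >= 3:
                try:
                    prob = float(fields[2])
                except ValueError:
                    prob = None
            sp[fields[0]] = (fields[1] != "OTHER", prob)

    tm: dict[str, tuple[int, tuple[tuple[int, int], ...]]] = {}
    with open(tmhmm_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split()
            m = _PREDHEL_RE.search(line)
            if m is None:
                raise FormatError(f"{tmhmm_path}:{lineno}: missing or unparsable PredHel field")
            n_helix = int(m.group(1))
            topo = _TOPO_RE.search(line)
            spans = parse_topology(topo.group(1)) if topo else None
            tm[fields[0]] = (n_helix, spans)

    merged: dict[str, SecretionEvidence] = {}
    for pid in sorted(set(sp) | set(tm)):
        sp_call, sp_prob = sp.get(pid, (False, None))
        n_helix, spans = tm.get(pid, (0, None))
        merged[pid] = SecretionEvidence(pid, sp_call, sp_prob, n_helix, spans)
    return merged


# ---------------------------------------------------------------------------
# writers (TSV with a '#'-commented header; '.' marks a missing value)
# ---------------------------------------------------------------------------

def write_domain_annotations(annotations: Iterable[DomainAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# protein_id\tdomain_acc\tdomain_name\tevalue\tenv_start\tenv_end\n")
        for a in sorted(annotations, key=lambda x: (x.protein_id, x.domain_acc,
                                                    x.envelope_start or 0)):
            fh.write(
                "\t".join(
                    [
                        a.protein_id,
                        a.domain_acc,
                        a.domain_name,
                        "." if a.evalue is None else repr(a.evalue),
                        "." if a.envelope_start is None else str(a.envelope_start),
                        "." if a.envelope_end is None else str(a.envelope_end),
                    ]
                )
                + "\n"
            )


def write_ddi_table(table: DDITable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# domain_a\tdomain_b\tconfidence\n")
        for e in table:
            fh.write(f"{e.domain_a}\t{e.domain_b}\t{e.confidence}\n")


def write_secretion_evidence(evidence: Iterable[SecretionEvidence], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# protein_id\tsp_call\tsp_probability\ttm_helix_count\ttm_helix_spans\n")
        for ev in sorted(evidence, key=lambda e: e.protein_id):
            spans = (
                "."
                if ev.tm_helix_spans is None
                else ";".join(f"{s}-{e}" for s, e in ev.tm_helix_spans) or "-"
            )
            fh.write(
                f"{ev.protein_id}\t{int(ev.sp_call)}\t"
                f"{'.' if ev.sp_probability is None else repr(ev.sp_probability)}\t"
                f"{ev.tm_helix_count}\t{spans}\n"
            )


def read_secretion_evidence(path: str | Path) -> dict[str, SecretionEvidence]:
    """Read the TSV dialect produced by :func:`write_secretion_evidence`."""
    out: dict[str, SecretionEvidence] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise FormatError(f"{path}:{lineno}: expected 5 columns")
            spans: Optional[tuple[tuple[int, int], ...]]
            if fields[4] == ".":
                spans = None
            elif fields[4] == "-":
                spans = ()
            else:
                spans = tuple(
                    (int(s), int(e))
                    for s, e in (part.split("-") for part in fields[4].split(";"))
                )
            out[fields[0]] = SecretionEvidence(
                protein_id=fields[0],
                sp_call=bool(int(fields[1])),
                sp_probability=None if fields[2] == "." else float(fields[2]),
                tm_helix_count=int(fields[3]),
                tm_helix_spans=spans,
            )
    return out


def write_proteome(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write proteins with sequences as FASTA (records without sequences rejected)."""
    with open(path, "w") as fh:
        for rec in sorted(records, key=lambda r: r.protein_id):
            if rec.sequence is None:
                raise ValidationError(f"protein {rec.protein_id} has no sequence to write")
            fh.write(f">{rec.protein_id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")
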