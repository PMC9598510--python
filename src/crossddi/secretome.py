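"""Secreted-protein nomination by signal-peptide / transmembrane subtraction.

A protein is called secreted when a signal peptide is predicted *and* it has
no (effective) transmembrane helix.  The default is the strict subtraction
rule — any predicted helix disqualifies.  Because signal peptides are often
mis-predicted as a first transmembrane helix, an optional N-terminal exemption
discounts helices lying entirely within the first ``nterm_exempt_len``
residues; it is off (0) by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from crossddi.core_io import SecretionEvidence, ValidationError

SP_AND_NO_TM = "SP_AND_NO_TM"
NO_SP = "NO_SP"
HAS_TM = "HAS_TM"
SP_TM_EXEMPTED = "SP_TM_EXEMPTED"


@dataclass(frozen=True)
class SecretionCall:
    protein_id: str
    is_secreted: bool
    reason: str

    def __post_init__(self) -> None:
        if self.reason not in (SP_AND_NO_TM, NO_SP, HAS_TM, SP_TM_EXEMPTED):
            raise ValidationError(f"{self.protein_id}: unknown reason {self.reason!r}")
        if self.is_secreted != (self.reason in (SP_AND_NO_TM, SP_TM_EXEMPTED)):
            raise ValidationError(f"{self.protein_id}: is_secreted inconsistent with reason")


def _effective_helix_count(ev: SecretionEvidence, nterm_exempt_len: int) -> int:
    if nterm_exempt_len <= 0 or ev.tm_helix_spans is None:
        return ev.tm_helix_count
    return sum(1 for s, e in ev.tm_helix_spans if e > nterm_exempt_len)


def call_secreted(
    evidence: Iterable[SecretionEvidence] | Mapping[str, SecretionEvidence],
    nterm_exempt_len: int = 0,
) -> dict[str, SecretionCall]:
    """Classify each protein with evidence as secreted or not, with a reason.

    Proteins lacking any evidence record are simply absent from the result
    (treat missing as non-secreted downstream).
    """
    if nterm_exempt_len < 0:
        raise ValidationError("nterm_exempt_len must be >= 0")
    if isinstance(evidence, Mapping):
        evidence = evidence.values()
    calls: dict[str, SecretionCall] = {}
    for ev in evidence:
        if not ev.sp_call:
            call = SecretionCall(ev.protein_id, False, NO_SP)
        else:
            effective = _effective_helix_count(ev, nterm_exempt_len)
            if effective == 0:
                reason = SP_TM_EXEMPTED if ev.tm_helix_count > 0 else SP_AND_NO_TM
                call = SecretionCall(ev.protein_id, True, reason)
            else:
                call = SecretionCall(ev.protein_id, False, HAS_TM)
        calls[ev.protein_id] = call
    return calls


def secreted_tsg_hubs(
    secretion_calls: Mapping[str, SecretionCall],
    hub_protein_ids: Iterable[str],
) -> set[str]:
    """TSG-hub proteins that are also called secreted (exact intersection)."""
    secreted = {pid for pid, c in secretion_calls.items() if c.is_secreted}
    return secreted & set(hub_protein_ids)


def write_secretion_calls(calls: Mapping[str, SecretionCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# protein_id\tis_secreted\treason\n")
        for pid in sorted(calls):
            c = calls[pid]
            fh.write(f"{pid}\t{int(c.is_secreted)}\t{c.reason}\n")
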