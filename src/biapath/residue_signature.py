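"""Active-site signature classification of AAAD-family protein sequences.

Insect DHPAAS (aldehyde synthase) and DDC (decarboxylase) are close
homologues distinguished by three active-site residues, numbered in the
B. mori / D. melanogaster reference frame: Phe79-Tyr80 with Asn192 marks an
aldehyde synthase, the reversed Tyr79-Phe80 with His192 marks a canonical
decarboxylase, and mixed triads (e.g. the Tyr79-Tyr80 of Drosophila isoform
X2 sequences) indicate intermediate, tunable chemistry.

A query is globally aligned to a reference of known numbering, the residues
aligned to reference positions 79/80/192 are read off, and a rule table maps
the triad to a functional class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")
GAP = "-"

DHPAAS_TRIAD = ("F", "Y", "N")
DDC_TRIAD = ("Y", "F", "H")
TRIAD_POSITIONS = (79, 80, 192)


class SequenceError(ValueError):
    """Empty sequence or residue outside the allowed alphabet."""


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    residues: str

    def __post_init__(self):
        if not self.residues:
            raise SequenceError(f"{self.id}: empty sequence")
        bad = set(self.residues.upper()) - AA_ALPHABET - {"X"}
        if bad:
            raise SequenceError(f"{self.id}: non-canonical residues {sorted(bad)}")
        object.__setattr__(self, "residues", self.residues.upper())

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class AlignmentResult:
    """Global alignment of a query against the numbering reference.

    ``ref_to_query`` maps 1-based reference positions to 0-based query
    indices (or None where the query has a gap).
    """

    query: SequenceRecord
    reference: SequenceRecord
    aligned_query: str
    aligned_reference: str
    score: float
    ref_to_query: dict[int, int | None] = field(default_factory=dict)


@dataclass(frozen=True)
class SignatureCall:
    id: str
    residue_79: str
    residue_80: str
    residue_192: str
    label: str  # DHPAAS-like | DDC-like | intermediate | undetermined
    note: str = ""


_ALIGNER = None


def _aligner() -> PairwiseAligner:
    """Shared global aligner: BLOSUM62, gap open 10, extend 1.

    A gap of length L scores -(10 + L); end gaps are penalised (true global
    alignment).
    """
    global _ALIGNER
    if _ALIGNER is None:
        a = PairwiseAligner()
        a.mode = "global"
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        a.open_gap_score = -11.0   # first gap residue: open(10) + extend(1)
        a.extend_gap_score = -1.0
        _ALIGNER = a
    return _ALIGNER


def global_align(query: SequenceRecord, reference: SequenceRecord) -> AlignmentResult:
    """Optimal global alignment of query vs. reference.

    Ties are broken deterministically by taking the aligner's first optimal
    alignment (its enumeration order is fixed, preferring diagonal moves).
    """
    alns = _aligner().align(query.residues, reference.residues)
    aln = alns[0]
    aq, ar = str(aln[0]), str(aln[1])
    mapping: dict[int, int | None] = {}
    qi = ri = 0
    for cq, cr in zip(aq, ar):
        if cr != GAP:
            ri += 1
            mapping[ri] = qi if cq != GAP else None
        if cq != GAP:
            qi += 1
    return AlignmentResult(query=query, reference=reference,
                           aligned_query=aq, aligned_reference=ar,
                           score=float(aln.score), ref_to_query=mapping)


def residues_at_positions(aln: AlignmentResult,
                          positions: Iterable[int] = TRIAD_POSITIONS) -> list[str]:
    """Query residues aligned to 1-based reference positions (gap -> '-')."""
    out = []
    for pos in positions:
        if not (1 <= pos <= len(aln.reference)):
            raise ValueError(f"position {pos} outside reference length "
                             f"{len(aln.reference)}")
        qi = aln.ref_to_query.get(pos)
        out.append(GAP if qi is None else aln.query.residues[qi])
    return out


def classify_signature(res79: str, res80: str, res192: str,
                       seq_id: str = "") -> SignatureCall:
    """Map an active-site triad to a functional class.

    (F,Y,N) -> DHPAAS-like; (Y,F,H) -> DDC-like; any other combination of
    F/Y at 79-80 with N/H at 192 -> intermediate, with a note saying which
    positions match which archetype.  Gaps, X, or residues outside the
    archetype sets -> undetermined.
    """
    triad = (res79, res80, res192)
    in_archetype = (res79 in "FY" and res80 in "FY" and res192 in "NH")
    if not in_archetype:
        bad = [f"pos{p}={r}" for p, r in zip(TRIAD_POSITIONS, triad)
               if r not in ("FY" if p != 192 else "NH")]
        return SignatureCall(seq_id, *triad, label="undetermined",
                             note="non-archetype residues: " + ", ".join(bad))
    if triad == DHPAAS_TRIAD:
        return SignatureCall(seq_id, *triad, label="DHPAAS-like",
                             note="Phe79-Tyr80 motif with Asn192")
    if triad == DDC_TRIAD:
        return SignatureCall(seq_id, *triad, label="DDC-like",
                             note="reversed Tyr79-Phe80 motif with His192")
    matches = []
    for pos, r, d_res, c_res in zip(TRIAD_POSITIONS, triad,
                                    DHPAAS_TRIAD, DDC_TRIAD):
        if r == d_res:
            matches.append(f"pos{pos} synthase-archetype")
        elif r == c_res:
            matches.append(f"pos{pos} decarboxylase-archetype")
        else:
            matches.append(f"pos{pos} mixed ({res79}{res80} motif)")
    return SignatureCall(seq_id, *triad, label="intermediate",
                         note="; ".join(matches))


def classify_record(query: SequenceRecord,
                    reference: SequenceRecord) -> SignatureCall:
    """Align one query to the reference and classify its triad."""
    aln = global_align(query, reference)
    r79, r80, r192 = residues_at_positions(aln, TRIAD_POSITIONS)
    call = classify_signature(r79, r80, r192, seq_id=query.id)
    return call


def classify_fasta(fasta_path, reference: SequenceRecord) -> pd.DataFrame:
    """Classify every record in a FASTA file; returns a tidy table."""
    rows = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        call = classify_record(SequenceRecord(rec.id, str(rec.seq)), reference)
        rows.append({"id": call.id, "res79": call.residue_79,
                     "res80": call.residue_80, "res192": call.residue_192,
                     "label": call.label, "note": call.note})
    return pd.DataFrame(rows, columns=["id", "res79", "res80", "res192",
                                       "label", "note"])
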