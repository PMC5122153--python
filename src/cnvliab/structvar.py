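"""Sequence-level characterization of a deletion CNV.

Covers the four wet-lab-adjacent computations around a deleted-type CNV:

* locating the same-orientation homology arms that mark a non-allelic
  homologous recombination (NAHR) junction, with the breakpoint reported as
  an ambiguity interval of arm length;
* deletion-length arithmetic under both the end-minus-start (difference)
  and inclusive conventions, which genome reports mix freely;
* the transcript/protein consequence of deleting internal exons, including
  intron retention and frameshift detection;
* copy-number estimation from qPCR Ct values by the 2 x 2^-ddCT method
  against a two-copy calibrator.

Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio import SeqIO

__all__ = [
    "JunctionModel",
    "GeneModel",
    "TranscriptConsequence",
    "QpcrMeasurement",
    "find_homology_arms",
    "deletion_length",
    "predict_transcript_consequence",
    "ddct_copy_number",
    "read_fasta",
]

#: average amino-acid residue mass, kDa (approximate protein mass = aa * this)
RESIDUE_MASS_KDA = 0.111


def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


@dataclass(frozen=True)
class JunctionModel:
    """An NAHR deletion junction (1-based inclusive coordinates).

    The two reference arm copies are identical and same-orientation; the
    breakpoint cannot be placed more precisely than an interval of arm
    length.  ``deletion_length`` follows the difference convention between
    the arm-adjacent (left-most-placement) bounds, i.e. right arm end minus
    left arm end.
    """

    left_arm: tuple | None
    right_arm: tuple | None
    arm_sequence: str
    deletion_length: int
    ambiguity: int
    chrom: str = "ref"

    @property
    def arm_length(self) -> int:
        return len(self.arm_sequence)

    def to_dict(self) -> dict:
        return {
            "chrom": self.chrom,
            "left_arm": list(self.left_arm) if self.left_arm else None,
            "right_arm": list(self.right_arm) if self.right_arm else None,
            "arm_sequence": self.arm_sequence,
            "arm_length": self.arm_length,
            "deletion_length": self.deletion_length,
            "ambiguity": self.ambiguity,
        }


def _extend_match(a: str, b: str, i: int, j: int, direction: int) -> int:
    """Length of the exact match extending from a[i]/b[j] in +-1 direction."""
    k = 0
    while 0 <= i < len(a) and 0 <= j < len(b) and a[i] == b[j]:
        k += 1
        i += direction
        j += direction
    return k


def find_homology_arms(reference: str, junction_read: str, anchor_min: int = 20) -> JunctionModel:
    """Locate the NAHR homology arms from a read spanning the junction.

    The read's first and last ``anchor_min`` bases are anchored exactly in
    the reference; each anchor is extended maximally.  The overlap of the
    two extended alignments on the read is the homology arm shared by both
    reference flanks; its length equals the breakpoint ambiguity.  A read
    whose anchors place it contiguously (no deleted bases between the
    alignments) raises "no junction found"; an end anchor matching only the
    reverse strand raises "not NAHR-compatible".
    """
    ref = str(reference).upper()
    read = str(junction_read).upper()
    if len(read) < 2 * anchor_min:
        raise ValueError("junction read shorter than two anchors")

    left_anchor = read[:anchor_min]
    right_anchor = read[-anchor_min:]
    l0 = ref.find(left_anchor)
    r_end = ref.rfind(right_anchor)
    if l0 < 0 or r_end < 0:
        rc = str(Seq(ref).reverse_complement())
        if (l0 < 0 and rc.find(left_anchor) >= 0) or (r_end < 0 and rc.find(right_anchor) >= 0):
            raise ValueError("not NAHR-compatible (same-directed arms required)")
        raise ValueError("no junction found: anchors do not align to the reference")

    # extend the left alignment rightwards from the anchor
    p = anchor_min + _extend_match(read, ref, anchor_min, l0 + anchor_min, +1)
    # extend the right alignment leftwards from its anchor
    right_read_start = len(read) - anchor_min
    ext = _extend_match(read, ref, right_read_start - 1, r_end - 1, -1)
    q = right_read_start - ext
    r0 = r_end - ext  # reference start (0-based) of the right alignment

    deleted_bases = (r0 + q) - (l0 + p)  # reference bases absent from the read
    if deleted_bases <= 0:
        raise ValueError("no junction found: read aligns contiguously")
    if q > p:
        # alignments do not meet: bases q..p of the read match neither flank
        raise ValueError("no junction found: unaligned bases at the junction")

    arm_len = p - q
    arm_seq = read[q:p]
    # 1-based inclusive coordinates; left-most breakpoint placement
    left_arm = (l0 + q + 1, l0 + p) if arm_len else None
    right_arm = (r0 + 1, r0 + arm_len) if arm_len else None
    left_end = l0 + p          # 1-based end of the left arm (or left flank)
    right_end = r0 + arm_len   # 1-based end of the right arm copy
    return JunctionModel(
        left_arm=left_arm,
        right_arm=right_arm,
        arm_sequence=arm_seq,
        deletion_length=right_end - left_end,
        ambiguity=arm_len,
    )


def deletion_length(start: int, end: int, convention: str = "difference") -> int:
    """end - start (difference) or end - start + 1 (inclusive).

    Reports of the same locus mix both conventions (a deletion quoted as the
    difference of its bounds, a homology arm as an inclusive base count), so
    the caller chooses explicitly.
    """
    if end <= start:
        raise ValueError("end must exceed start")
    if convention == "difference":
        return end - start
    if convention == "inclusive":
        return end - start + 1
    raise ValueError("convention must be 'difference' or 'inclusive'")


@dataclass(frozen=True)
class GeneModel:
    """Exon structure of a gene (1-based inclusive genomic coordinates)."""

    gene_id: str
    strand: str
    exons: list
    cds_start: int
    cds_end: int
    sequence: str | None = None  # chromosome sequence, optional

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        ex = sorted(self.exons)
        if list(self.exons) != ex:
            raise ValueError("exons must be ordered")
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if s2 <= e1:
                raise ValueError("exons must not overlap")
        if not any(s <= self.cds_start <= e for s, e in self.exons):
            raise ValueError("CDS start must fall inside an exon")
        if not any(s <= self.cds_end <= e for s, e in self.exons):
            raise ValueError("CDS end must fall inside an exon")

    @property
    def introns(self) -> list:
        return [
            (e1 + 1, s2 - 1) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        ]

    @classmethod
    def from_exon_table(cls, path, sequence=None) -> "GeneModel":
        """GFF3-like TSV with columns gene_id, strand, start, end, feature."""
        df = pd.read_csv(path, sep="\t")
        exons = [
            (int(r.start), int(r.end))
            for r in df[df["feature"] == "exon"].itertuples()
        ]
        cds = df[df["feature"] == "CDS"]
        return cls(
            gene_id=str(df["gene_id"].iloc[0]),
            strand=str(df["strand"].iloc[0]),
            exons=sorted(exons),
            cds_start=int(cds["start"].min()),
            cds_end=int(cds["end"].max()),
            sequence=sequence,
        )


@dataclass(frozen=True)
class TranscriptConsequence:
    """Predicted effect of a deletion (plus retained introns) on a transcript."""

    retained_exons: list
    retained_introns: list
    frame: str                      # "in-frame" | "frameshift" | "null"
    cds_length: int | None
    protein_length_aa: int | None
    transcript_length: int
    is_null: bool

    @property
    def protein_mass_kda(self) -> float | None:
        """Approximate mass from the average residue mass; a prediction."""
        if self.protein_length_aa is None:
            return None
        return round(self.protein_length_aa * RESIDUE_MASS_KDA, 1)


def _overlap(a, b) -> int:
    lo = max(a[0], b[0])
    hi = min(a[1], b[1])
    return max(0, hi - lo + 1)


def predict_transcript_consequence(
    gene: GeneModel, deletion=None, retained_introns=None
) -> TranscriptConsequence:
    """Splice out exons lost to a deletion and evaluate the fused CDS.

    Exons fully inside the deletion are removed; the remaining exons are
    spliced in genomic order; retained introns (e.g. an intron that fails to
    splice in the mutant transcript) are inserted at their anatomical
    position.  The reading frame is evaluated on the fused CDS: protein
    length = in-frame CDS length / 3 minus the stop codon.  A null allele is
    flagged when the start codon is lost, all coding exons are removed, or
    (with sequence available) a premature stop truncates the protein below
    10% of wild type.  Exons only partially overlapped by the deletion are
    kept intact with a warning.
    """
    retained_introns = [tuple(r) for r in (retained_introns or [])]
    if deletion is None:
        removed = []
    else:
        removed = [
            ex for ex in gene.exons if deletion[0] <= ex[0] and ex[1] <= deletion[1]
        ]
        partial = [
            ex for ex in gene.exons
            if ex not in removed and _overlap(ex, deletion) > 0
        ]
        if partial:
            warnings.warn(
                f"deletion partially overlaps exon(s) {partial}; kept intact",
                stacklevel=2,
            )
    retained = [ex for ex in gene.exons if ex not in removed]
    cds_span = (gene.cds_start, gene.cds_end)
    transcript_length = sum(e - s + 1 for s, e in retained) + sum(
        e - s + 1 for s, e in retained_introns
    )

    start_exon = next(
        (ex for ex in gene.exons if ex[0] <= gene.cds_start <= ex[1]), None
    )
    coding_retained = [ex for ex in retained if _overlap(ex, cds_span) > 0]
    if start_exon in removed or not coding_retained:
        return TranscriptConsequence(
            retained, retained_introns, "null", None, None, transcript_length, True
        )

    cds_length = sum(_overlap(ex, cds_span) for ex in coding_retained)
    cds_length += sum(
        e - s + 1 for s, e in retained_introns if cds_span[0] <= s and e <= cds_span[1]
    )

    wild_cds = sum(_overlap(ex, cds_span) for ex in gene.exons)
    wild_aa = wild_cds // 3 - 1

    if gene.sequence is not None:
        protein_len, premature = _translate_fused(
            gene, retained, retained_introns
        )
        if protein_len is None or protein_len < 0.1 * wild_aa:
            return TranscriptConsequence(
                retained, retained_introns, "null", cds_length, protein_len,
                transcript_length, True,
            )
        frame = "in-frame" if (cds_length % 3 == 0 and not premature) else "frameshift"
        return TranscriptConsequence(
            retained, retained_introns, frame, cds_length, protein_len,
            transcript_length, False,
        )

    if cds_length % 3 == 0:
        return TranscriptConsequence(
            retained, retained_introns, "in-frame", cds_length,
            cds_length // 3 - 1, transcript_length, False,
        )
    return TranscriptConsequence(
        retained, retained_introns, "frameshift", cds_length, None,
        transcript_length, False,
    )


def _translate_fused(gene: GeneModel, retained, retained_introns):
    """Translate the fused transcript from the start codon; returns
    (protein length in aa excluding the stop, premature-stop flag)."""
    pieces = sorted(list(retained) + list(retained_introns))
    seq = "".join(gene.sequence[s - 1 : e] for s, e in pieces)

    def tx_coord(genomic):
        offset = 0
        for s, e in pieces:
            if s <= genomic <= e:
                return offset + (genomic - s)
            offset += e - s + 1
        return None

    if gene.strand == "-":
        pos = tx_coord(gene.cds_end)  # 5' end of the CDS on the minus strand
        if pos is None:
            return None, False
        tx = str(Seq(seq).reverse_complement())[len(seq) - 1 - pos :]
    else:
        start_tx = tx_coord(gene.cds_start)
        if start_tx is None:
            return None, False
        tx = seq[start_tx:]
    if not tx.startswith("ATG"):
        return None, False
    prot = str(Seq(tx[: len(tx) - len(tx) % 3]).translate(to_stop=True))
    full_codons = len(tx) // 3
    premature = len(prot) + 1 < full_codons  # stop before the final codon
    return len(prot), premature


@dataclass(frozen=True)
class QpcrMeasurement:
    """Replicate Ct values for one sample: target locus and the two-copy
    internal reference co-amplified in the same reactions."""

    sample_id: str
    target_ct: tuple
    reference_ct: tuple

    def __post_init__(self):
        if len(self.target_ct) < 1 or len(self.reference_ct) != len(self.target_ct):
            raise ValueError("need >= 1 paired target/reference Ct replicate")
        if any(c <= 0 for c in self.target_ct + self.reference_ct):
            raise ValueError("Ct values must be positive")

    @property
    def delta_ct(self) -> np.ndarray:
        return np.asarray(self.target_ct) - np.asarray(self.reference_ct)

    @classmethod
    def from_csv(cls, path) -> dict:
        """CSV with columns sample, replicate, target_ct, ref_ct."""
        df = pd.read_csv(path)
        out = {}
        for sid, grp in df.groupby("sample"):
            grp = grp.sort_values("replicate")
            out[sid] = cls(str(sid), tuple(grp["target_ct"]), tuple(grp["ref_ct"]))
        return out


def ddct_copy_number(sample: QpcrMeasurement, calibrator: QpcrMeasurement):
    """Copy number by the comparative Ct method: CN = 2 x 2^-ddCT.

    dCt = target Ct - reference Ct per replicate; ddCt = mean dCt(sample) -
    mean dCt(calibrator), the calibrator carrying two copies by assumption.
    The SEM is propagated to the copy-number scale by the delta method
    (SEM_CN = CN * ln 2 * SE(ddCt)).  Returns ``(copy_number, sem)``.
    """
    ds = sample.delta_ct
    dc = calibrator.delta_ct

    def sem(x):
        return float(np.std(x, ddof=1) / math.sqrt(len(x))) if len(x) > 1 else 0.0

    ddct = float(ds.mean() - dc.mean())
    se_ddct = math.hypot(sem(ds), sem(dc))
    cn = 2.0 * 2.0 ** (-ddct)
    return cn, cn * math.log(2.0) * se_ddct
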