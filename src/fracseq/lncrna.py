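"""lncRNA identification: filter cascade and dual coding-potential consensus.

Candidate transcripts must be multi-exonic, longer than 200 nt of spliced
sequence, stranded, expressed (TPM > 1 in at least one sample), and outside
repeat-masked regions. Surviving transcripts are partitioned by their class
code against the reference annotation: exact matches inherit the reference
biotype (lincRNA/antisense -> annotated lncRNA, protein_coding -> mRNA);
everything else is unannotated and kept as a lncRNA only if every required
coding-potential predictor calls it noncoding.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .catalog import TranscriptCatalog, TranscriptModel

logger = logging.getLogger(__name__)

LNCRNA_BIOTYPES = frozenset({"lincRNA", "antisense"})

CATEGORIES = (
    "annotated_lncRNA",
    "unannotated_lncRNA",
    "protein_coding",
    "rejected",
)


@dataclass(frozen=True)
class CodingPotentialLabel:
    transcript_id: str
    predictor_name: str
    label: str  # "noncoding" | "coding"

    def __post_init__(self):
        if self.label not in ("noncoding", "coding"):
            raise ValueError(f"invalid coding-potential label {self.label!r}")


@dataclass(frozen=True)
class TranscriptAnnotationStatus:
    transcript_id: str
    class_code: str
    reference_biotype: Optional[str]
    category: str
    rejection_reason: Optional[str] = None


class RepeatMask:
    """A set of repeat-masked genomic intervals, queryable for exonic overlap."""

    def __init__(self, intervals: Iterable[tuple[str, int, int]] = ()):
        per_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for chrom, start, end in intervals:
            if start >= end:
                raise ValueError(f"invalid mask interval [{start},{end}) on {chrom}")
            per_chrom[chrom].append((start, end))
        # merge per chromosome so overlap counting never double-counts
        self._merged: dict[str, list[tuple[int, int]]] = {}
        for chrom, ivs in per_chrom.items():
            ivs.sort()
            merged = [list(ivs[0])]
            for s, e in ivs[1:]:
                if s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            self._merged[chrom] = [tuple(m) for m in merged]

    def intervals(self) -> list[tuple[str, int, int]]:
        """Merged mask intervals as (chrom, start, end), sorted."""
        return [
            (chrom, s, e)
            for chrom in sorted(self._merged)
            for s, e in self._merged[chrom]
        ]

    @classmethod
    def from_bed(cls, path) -> "RepeatMask":
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track")):
                    continue
                fields = line.split("\t")
                rows.append((fields[0], int(fields[1]), int(fields[2])))
        return cls(rows)

    def overlap_fraction(self, t: TranscriptModel) -> float:
        """Fraction of the transcript's exonic bases inside the mask."""
        ivs = self._merged.get(t.chrom, [])
        if not ivs:
            return 0.0
        covered = 0
        for es, ee in t.exons:
            for ms, me in ivs:
                lo, hi = max(es, ms), min(ee, me)
                if lo < hi:
                    covered += hi - lo
        return covered / t.length


def filter_candidates(
    catalog: TranscriptCatalog,
    expr: pd.DataFrame,
    mask: RepeatMask | None = None,
    *,
    min_exons: int = 2,
    min_length: int = 200,
    tpm_threshold: float = 1.0,
    max_repeat_fraction: float = 0.0,
    expression_stat: str = "max",
    reasons: dict | None = None,
) -> set[str]:
    """Apply the candidate filter cascade; returns retained transcript_ids.

    A transcript is kept when it has >= ``min_exons`` exons, spliced length
    strictly greater than ``min_length`` nt, a known strand, expression
    (``max`` or ``mean`` TPM across samples) strictly greater than
    ``tpm_threshold``, and an exonic repeat-overlap fraction not exceeding
    ``max_repeat_fraction``. Transcripts absent from ``expr`` are treated as
    TPM 0 and logged. The filters commute: pass ``reasons`` a dict to receive
    the first failing filter per rejected transcript.

    Parameters
    ----------
    expr : DataFrame
        transcripts x samples TPM matrix indexed by transcript_id.
    """
    if mask is None:
        mask = RepeatMask()
    if expression_stat not in ("max", "mean"):
        raise ValueError(f"invalid expression_stat {expression_stat!r}")
    retained: set[str] = set()
    for tid in catalog.transcript_ids:
        t = catalog[tid]
        if tid in expr.index:
            vals = expr.loc[tid]
            level = float(vals.max() if expression_stat == "max" else vals.mean())
        else:
            logger.info("transcript %s missing from expression matrix; TPM set to 0", tid)
            level = 0.0
        reason = None
        if len(t.exons) < min_exons:
            reason = "mono-exonic" if min_exons == 2 else "too_few_exons"
        elif t.length <= min_length:
            reason = "short"
        elif t.strand == ".":
            reason = "unstranded"
        elif level <= tpm_threshold:
            reason = "low_expression"
        elif mask.overlap_fraction(t) > max_repeat_fraction:
            reason = "repeat_masked"
        if reason is None:
            retained.add(tid)
        elif reasons is not None:
            reasons[tid] = reason
    return retained


def classify_transcripts(
    candidates: set[str],
    codes: Mapping[str, tuple[str, Optional[str]]],
    cp_labels: Iterable[CodingPotentialLabel],
    required_predictors: Sequence[str],
) -> list[TranscriptAnnotationStatus]:
    """Partition candidates into the four annotation categories.

    ``codes`` maps transcript_id to (class_code, reference_biotype); the
    biotype is only meaningful for exact matches ("="). Unannotated
    transcripts are kept as lncRNAs only when every predictor in
    ``required_predictors`` labels them noncoding.
    """
    if not required_predictors:
        raise ValueError("at least one required predictor name is needed")
    labels: dict[str, dict[str, str]] = defaultdict(dict)
    for cp in cp_labels:
        labels[cp.transcript_id][cp.predictor_name] = cp.label

    missing_codes = sorted(tid for tid in candidates if tid not in codes)
    if missing_codes:
        raise ValueError(f"candidates missing class codes: {missing_codes}")

    unannotated = [tid for tid in candidates if codes[tid][0] != "="]
    missing = sorted(
        tid
        for tid in unannotated
        if any(p not in labels.get(tid, {}) for p in required_predictors)
    )
    if missing:
        raise ValueError(
            f"candidates missing required coding-potential labels: {missing}"
        )

    out = []
    for tid in sorted(candidates):
        code, biotype = codes[tid]
        if code == "=":
            if biotype in LNCRNA_BIOTYPES:
                out.append(TranscriptAnnotationStatus(tid, code, biotype, "annotated_lncRNA"))
            elif biotype == "protein_coding":
                out.append(TranscriptAnnotationStatus(tid, code, biotype, "protein_coding"))
            else:
                out.append(
                    TranscriptAnnotationStatus(
                        tid, code, biotype, "rejected", "annotated_other_biotype"
                    )
                )
        else:
            if all(labels[tid][p] == "noncoding" for p in required_predictors):
                out.append(TranscriptAnnotationStatus(tid, code, biotype, "unannotated_lncRNA"))
            else:
                out.append(
                    TranscriptAnnotationStatus(tid, code, biotype, "rejected", "coding_potential")
                )
    return out


_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")
STOP_CODONS = {"TAA", "TAG", "TGA"}


def _spliced_sequence(t: TranscriptModel, genome: Mapping[str, str]) -> str:
    seq = genome[t.chrom]
    for _, end in t.exons:
        if end > len(seq):
            raise ValueError(
                f"{t.transcript_id}: exon end {end} beyond chromosome {t.chrom} length {len(seq)}"
            )
    spliced = "".join(seq[s:e] for s, e in t.exons)
    if t.strand == "-":
        spliced = spliced.translate(_COMPLEMENT)[::-1]
    return spliced.upper()


def longest_orf_aa(seq: str) -> int:
    """Length in amino acids (codons, excluding the stop) of the longest
    ATG-initiated, stop-terminated ORF in the three forward frames."""
    best = 0
    n = len(seq)
    for frame in range(3):
        start = None
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in STOP_CODONS:
                best = max(best, (i - start) // 3)
                start = None
    return best


def builtin_orf_predictor(
    t: TranscriptModel,
    genome: Mapping[str, str],
    *,
    min_orf_aa: int = 100,
    predictor_name: str = "builtin_orf",
) -> CodingPotentialLabel:
    """Label a transcript coding/noncoding by its longest sense-strand ORF.

    A deliberately simple ORF-length rule over the spliced transcript
    sequence (reverse-complemented for minus-strand transcripts): coding iff
    the longest ATG..stop ORF is at least ``min_orf_aa`` amino acids.
    """
    spliced = _spliced_sequence(t, genome)
    label = "coding" if longest_orf_aa(spliced) >= min_orf_aa else "noncoding"
    return CodingPotentialLabel(t.transcript_id, predictor_name, label)


def read_cp_labels(path) -> list[CodingPotentialLabel]:
    """Read a predictor-label TSV (transcript_id, predictor, label)."""
    df = pd.read_csv(path, sep="\t")
    return [
        CodingPotentialLabel(row["transcript_id"], row["predictor"], row["label"])
        for _, row in df.iterrows()
    ]
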