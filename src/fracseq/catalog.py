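"""Transcript catalogs: data model, GTF I/O, and intron-chain comparison.

Coordinates are 0-based half-open internally; GTF I/O converts to/from the
1-based inclusive convention. Transcript equivalence throughout the package
is intron-chain identity on the same chromosome and strand: terminal exon
boundaries are assembler-sensitive, internal splice junctions are not.
Mono-exonic transcripts (no intron chain) are equivalent only on an exact
exon span.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

Interval = tuple[int, int]

STRANDS = ("+", "-", ".")

#: the transfrag class codes this package assigns, in precedence order
CLASS_CODES = ("=", "c", "j", "i", "x", "o", "u")


class GTFParseError(ValueError):
    """Raised for a malformed GTF record; carries the 1-based line number."""

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")


@dataclass(frozen=True)
class TranscriptModel:
    """An exon-structured transcript on a genome.

    exons are 0-based half-open intervals, sorted ascending, non-overlapping,
    with positive-length introns between adjacent exons. strand "." means
    unknown.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[Interval, ...]
    source_label: str = ""

    def __post_init__(self):
        if self.strand not in STRANDS:
            raise ValueError(f"{self.transcript_id}: invalid strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript has no exons")
        prev_end = None
        for start, end in self.exons:
            if start >= end:
                raise ValueError(
                    f"{self.transcript_id}: exon [{start},{end}) has start >= end"
                )
            if prev_end is not None and start <= prev_end:
                raise ValueError(
                    f"{self.transcript_id}: exons overlap or touch at {start}"
                )
            prev_end = end
        object.__setattr__(self, "exons", tuple(map(tuple, self.exons)))

    @property
    def length(self) -> int:
        """Spliced length: sum of exon lengths."""
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def is_multi_exonic(self) -> bool:
        return len(self.exons) > 1

    def intron_chain(self) -> tuple[Interval, ...]:
        """Gaps between consecutive exons; empty for mono-exonic transcripts."""
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )

    def chain_key(self) -> tuple:
        """Equivalence key: (chrom, strand, intron chain), exact span if mono-exonic."""
        if self.is_multi_exonic:
            return (self.chrom, self.strand, self.intron_chain())
        return (self.chrom, self.strand, ("mono",) + self.span)

    @property
    def tss(self) -> int:
        """Position of the 5' end (leftmost base on +, rightmost on -)."""
        if self.strand == "+":
            return self.exons[0][0]
        if self.strand == "-":
            return self.exons[-1][1]
        raise ValueError(f"{self.transcript_id}: TSS undefined for unknown strand")


class TranscriptCatalog:
    """A collection of TranscriptModel keyed by transcript_id with a gene index."""

    def __init__(self, transcripts: Iterable[TranscriptModel] = ()):
        self._transcripts: dict[str, TranscriptModel] = {}
        self._gene_index: dict[str, list[str]] = defaultdict(list)
        for t in transcripts:
            self.add(t)

    def add(self, t: TranscriptModel) -> None:
        if t.transcript_id in self._transcripts:
            raise ValueError(f"duplicate transcript_id {t.transcript_id!r}")
        self._transcripts[t.transcript_id] = t
        self._gene_index[t.gene_id].append(t.transcript_id)

    def __len__(self) -> int:
        return len(self._transcripts)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self._transcripts.values())

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self._transcripts

    def __getitem__(self, transcript_id: str) -> TranscriptModel:
        return self._transcripts[transcript_id]

    @property
    def transcript_ids(self) -> list[str]:
        return list(self._transcripts)

    @property
    def gene_index(self) -> Mapping[str, list[str]]:
        return dict(self._gene_index)

    def by_chrom(self) -> Mapping[str, list[TranscriptModel]]:
        out: dict[str, list[TranscriptModel]] = defaultdict(list)
        for t in self:
            out[t.chrom].append(t)
        return out

    def chain_keys(self) -> set[tuple]:
        return {t.chain_key() for t in self}


@dataclass(frozen=True)
class AssemblySupport:
    """Per-condition count of sample assemblies containing a transcript."""

    transcript_id: str
    tumor_support: int
    adjacent_support: int


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(attr_field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def read_catalog(path, dialect: str = "gtf") -> TranscriptCatalog:
    """Read a GTF file into a TranscriptCatalog.

    Only ``exon`` features are used to build transcripts; ``transcript``
    records are accepted and ignored. GTF 1-based inclusive coordinates are
    converted to 0-based half-open. Strand "." maps to unknown.
    """
    if dialect != "gtf":
        raise ValueError(f"unsupported dialect {dialect!r}")
    exon_rows: dict[str, list[tuple[int, int]]] = defaultdict(list)
    meta: dict[str, tuple[str, str, str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GTFParseError(lineno, f"expected 9 tab-separated fields, got {len(fields)}")
            chrom, source, feature, start_s, end_s, _score, strand, _frame, attrs_s = fields
            if feature != "exon":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise GTFParseError(lineno, f"non-integer coordinates {start_s!r}/{end_s!r}")
            if end1 < start1:
                raise GTFParseError(lineno, f"end {end1} < start {start1}")
            if strand not in STRANDS:
                raise GTFParseError(lineno, f"invalid strand {strand!r}")
            attrs = _parse_attributes(attrs_s)
            if "transcript_id" not in attrs or "gene_id" not in attrs:
                raise GTFParseError(lineno, "missing transcript_id or gene_id attribute")
            tid = attrs["transcript_id"]
            exon_rows[tid].append((start1 - 1, end1))  # to 0-based half-open
            prev = meta.get(tid)
            record = (attrs["gene_id"], chrom, strand, source)
            if prev is not None and prev[:3] != record[:3]:
                raise GTFParseError(lineno, f"inconsistent gene/chrom/strand for {tid!r}")
            meta[tid] = record
    catalog = TranscriptCatalog()
    for tid, exons in exon_rows.items():
        gene_id, chrom, strand, source = meta[tid]
        catalog.add(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gene_id,
                chrom=chrom,
                strand=strand,
                exons=tuple(sorted(exons)),
                source_label=source,
            )
        )
    return catalog


def write_catalog(catalog: TranscriptCatalog, path) -> None:
    """Write a catalog as GTF (transcript + exon features, 1-based inclusive)."""
    with open(path, "w") as fh:
        for tid in sorted(catalog.transcript_ids):
            t = catalog[tid]
            source = t.source_label or "fracseq"
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            s, e = t.span
            fh.write(
                f"{t.chrom}\t{source}\ttranscript\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
            )
            for es, ee in t.exons:
                fh.write(
                    f"{t.chrom}\t{source}\texon\t{es + 1}\t{ee}\t.\t{t.strand}\t.\t{attrs}\n"
                )


def _intervals_overlap(a: Interval, b: Interval) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _exonic_overlap(a: TranscriptModel, b: TranscriptModel) -> bool:
    return any(_intervals_overlap(ea, eb) for ea in a.exons for eb in b.exons)


def _is_contiguous_subchain(sub: Sequence[Interval], full: Sequence[Interval]) -> bool:
    n, m = len(sub), len(full)
    if n == 0 or n > m:
        return False
    sub = tuple(sub)
    return any(tuple(full[i : i + n]) == sub for i in range(m - n + 1))


def assign_class_code(query: TranscriptModel, reference: TranscriptCatalog) -> str:
    """Assign a transfrag class code to ``query`` against a reference catalog.

    Precedence: "=" identical intron chain (same strand); "c" contained
    contiguous sub-chain within the reference span; "j" at least one shared
    splice junction; "i" entirely within a reference intron (either strand);
    "x" exonic overlap only on the opposite strand; "o" any same-strand
    exonic overlap; "u" intergenic.
    """
    if query.strand == ".":
        raise ValueError(
            f"{query.transcript_id}: class codes require known strand"
        )
    q_lo, q_hi = query.span
    # every non-"u" relation requires reference-span overlap with the query span
    same_chrom = [
        r
        for r in reference
        if r.chrom == query.chrom and r.span[0] < q_hi and q_lo < r.span[1]
    ]
    q_chain = query.intron_chain()
    q_junctions = set(q_chain)
    q_span = query.span

    same_strand = [r for r in same_chrom if r.strand == query.strand]
    opposite = [r for r in same_chrom if r.strand not in (query.strand, ".")]

    for r in same_strand:
        if r.is_multi_exonic and r.intron_chain() == q_chain:
            return "="
    for r in same_strand:
        r_chain = r.intron_chain()
        r_span = r.span
        if (
            _is_contiguous_subchain(q_chain, r_chain)
            and r_span[0] <= q_span[0]
            and q_span[1] <= r_span[1]
        ):
            return "c"
    for r in same_strand:
        if q_junctions & set(r.intron_chain()):
            return "j"
    for r in same_chrom:
        for intron in r.intron_chain():
            if intron[0] <= q_span[0] and q_span[1] <= intron[1]:
                return "i"
    same_strand_overlap = any(_exonic_overlap(query, r) for r in same_strand)
    opposite_overlap = any(_exonic_overlap(query, r) for r in opposite)
    if opposite_overlap and not same_strand_overlap:
        return "x"
    if same_strand_overlap:
        return "o"
    return "u"


def assign_class_codes(
    queries: TranscriptCatalog, reference: TranscriptCatalog
) -> dict[str, str]:
    """assign_class_code for every multi-exonic stranded query transcript."""
    return {
        t.transcript_id: assign_class_code(t, reference)
        for t in queries
        if t.is_multi_exonic and t.strand != "."
    }


def intersect_assemblies(a: TranscriptCatalog, b: TranscriptCatalog) -> TranscriptCatalog:
    """Transcripts of ``a`` whose (chrom, strand, intron chain) occurs in ``b``.

    Keeps ``a``'s identifiers; terminal exon ends of multi-exonic transcripts
    need not match.
    """
    b_keys = b.chain_keys()
    return TranscriptCatalog(t for t in a if t.chain_key() in b_keys)


def assembly_support(
    t: TranscriptModel,
    sample_catalogs: Sequence[tuple[TranscriptCatalog, str]],
) -> AssemblySupport:
    """Count sample assemblies containing ``t``, separately per condition.

    Condition labels must be "tumor" or "adjacent". Containment is
    chain-key identity (chrom, strand, intron chain).
    """
    key = t.chain_key()
    counts = {"tumor": 0, "adjacent": 0}
    for catalog, condition in sample_catalogs:
        if condition not in counts:
            raise ValueError(f"unknown condition label {condition!r}")
        if key in catalog.chain_keys():
            counts[condition] += 1
    return AssemblySupport(t.transcript_id, counts["tumor"], counts["adjacent"])


def assembly_support_table(
    targets: TranscriptCatalog,
    sample_catalogs: Sequence[tuple[TranscriptCatalog, str]],
) -> list[AssemblySupport]:
    """Vectorized assembly_support for every transcript in ``targets``.

    Precomputes each sample catalog's chain-key set once, so the cost is
    O(samples x catalog size + targets) rather than per-target rescans.
    """
    keysets = []
    for catalog, condition in sample_catalogs:
        if condition not in ("tumor", "adjacent"):
            raise ValueError(f"unknown condition label {condition!r}")
        keysets.append((catalog.chain_keys(), condition))
    out = []
    for tid in sorted(targets.transcript_ids):
        key = targets[tid].chain_key()
        tumor = sum(1 for keys, cond in keysets if cond == "tumor" and key in keys)
        adjacent = sum(1 for keys, cond in keysets if cond == "adjacent" and key in keys)
        out.append(AssemblySupport(tid, tumor, adjacent))
    return out
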