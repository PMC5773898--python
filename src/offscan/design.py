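"""sgRNA design from coding sequences, and paired-nickase pair design.

Guides are 20-base protospacers immediately 5' of a primary PAM (NGG for
SpCas9), designed on either strand of the spliced CDS.  Editing by indel
formation works best near the start codon, so candidates are restricted to
the first half of the CDS; guides containing a run of four T (a Pol III
terminator) or four A are rejected.  GC content correlates with activity
and is reported on every guide; bounds are optional and off by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

from .genome_io import (
    PAM_LEN,
    PROTOSPACER_LEN,
    PamPolicy,
    SequenceRecord,
    find_pam_adjacent_sites,
    reverse_complement,
)

__all__ = [
    "GuideRNA",
    "DesignRules",
    "GuidePair",
    "gc_content",
    "has_forbidden_run",
    "design_guides",
    "design_pairs",
    "guides_to_tsv",
    "guides_to_bed6_rows",
    "cds_from_bed",
    "cds_from_gff3",
]


def gc_content(seq: str) -> float:
    """(G + C count) / length, in [0, 1]."""
    if not seq:
        raise ValueError("empty sequence")
    return (seq.count("G") + seq.count("C")) / len(seq)


@dataclass(frozen=True)
class GuideRNA:
    """A 20-base protospacer with its PAM and genomic placement.

    ``protospacer`` is read 5'->3' on the guide's own strand; ``start``/``end``
    is the plus-strand half-open interval the protospacer occupies on
    ``source_id``; the PAM sits immediately 3' of the protospacer on the
    guide's strand.
    """

    protospacer: str
    pam: str
    source_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if len(self.protospacer) != PROTOSPACER_LEN or set(self.protospacer) - set("ACGT"):
            raise ValueError("protospacer must be a 20-base ACGT string")
        if len(self.pam) != PAM_LEN:
            raise ValueError("PAM must be 3 bases")
        if self.end - self.start != PROTOSPACER_LEN:
            raise ValueError("protospacer interval must span 20 bases")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")

    @property
    def gc(self) -> float:
        return gc_content(self.protospacer)

    @property
    def seed(self) -> str:
        return self.protospacer[-12:]

    @property
    def five_prime_end(self) -> int:
        """Plus-strand coordinate of the protospacer's 5' base."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def name(self) -> str:
        return f"{self.source_id}:{self.start}-{self.end}({self.strand})"


@dataclass
class DesignRules:
    """Filters applied when designing guides from a CDS."""

    region_fraction: float = 0.5  # protospacer must lie in [0, ceil(L * fraction))
    forbid_runs: frozenset = frozenset({"TTTT", "AAAA"})
    gc_min: Optional[float] = None  # report-only unless set
    gc_max: Optional[float] = None
    pam_policy: PamPolicy = field(
        default_factory=lambda: PamPolicy(use_secondary=False)
    )

    def __post_init__(self) -> None:
        self.forbid_runs = frozenset(self.forbid_runs)
        for run in self.forbid_runs:
            if len(run) < 4 or len(set(run)) != 1:
                raise ValueError(f"forbidden run must be a homopolymer >= 4: {run!r}")
        if not 0 < self.region_fraction <= 1:
            raise ValueError("region_fraction must be in (0, 1]")


def has_forbidden_run(seq: str, rules: DesignRules | None = None) -> bool:
    """True iff any forbidden homopolymer run occurs in ``seq`` as written."""
    rules = rules or DesignRules()
    return any(run in seq for run in rules.forbid_runs)


def design_guides(cds: SequenceRecord, rules: DesignRules | None = None) -> List[GuideRNA]:
    """All guides passing the design rules on both strands of a spliced CDS.

    A guide requires a primary PAM immediately 3' of the protospacer on its
    own strand; the whole protospacer (not the PAM) must lie inside the first
    ``region_fraction`` of the CDS; the protospacer, as written 5'->3', must
    not contain a forbidden run (a minus-strand guide is checked on its own
    sequence, so plus-strand TTTT forbids the corresponding AAAA guide only
    if the guide itself carries a run).  Output is deterministic, ordered by
    start then strand.
    """
    rules = rules or DesignRules()
    L = cds.length
    if L < PROTOSPACER_LEN + PAM_LEN:
        return []
    region_end = math.ceil(L * rules.region_fraction)
    design_pam = PamPolicy(primary=rules.pam_policy.primary, use_secondary=False)
    guides: List[GuideRNA] = []
    for pam_start, strand, _cls in find_pam_adjacent_sites(cds, design_pam):
        if strand == "+":
            start, end = pam_start - PROTOSPACER_LEN, pam_start
            protospacer = cds.seq[start:end]
            pam = cds.seq[pam_start : pam_start + PAM_LEN]
        else:
            start, end = pam_start + PAM_LEN, pam_start + PAM_LEN + PROTOSPACER_LEN
            protospacer = reverse_complement(cds.seq[start:end])
            pam = reverse_complement(cds.seq[pam_start : pam_start + PAM_LEN])
        if end > region_end:
            continue
        if has_forbidden_run(protospacer, rules):
            continue
        gc = gc_content(protospacer)
        if rules.gc_min is not None and gc < rules.gc_min:
            continue
        if rules.gc_max is not None and gc > rules.gc_max:
            continue
        guides.append(
            GuideRNA(protospacer=protospacer, pam=pam, source_id=cds.id,
                     start=start, end=end, strand=strand)
        )
    guides.sort(key=lambda g: (g.start, g.strand))
    return guides


@dataclass(frozen=True)
class GuidePair:
    """Two opposite-strand guides for Cas9-nickase paired nicking.

    ``offset`` is the distance between the two protospacers' 5' ends in
    plus-strand coordinates, signed as (5' end of the leftward-PAM guide)
    minus (5' end of the rightward-PAM guide), so head-to-head PAM-out
    designs with overlapping 5' ends have small positive offsets.  Paired
    nicking works well for offsets in [-4, 20].
    """

    left: GuideRNA
    right: GuideRNA
    offset: int

    def __post_init__(self) -> None:
        if self.left.strand == self.right.strand:
            raise ValueError("paired guides must target opposite strands")


def _pair_offset(a: GuideRNA, b: GuideRNA) -> int:
    minus, plus = (a, b) if a.strand == "-" else (b, a)
    return minus.five_prime_end - plus.five_prime_end


def design_pairs(
    guides: Sequence[GuideRNA], min_offset: int = -4, max_offset: int = 20
) -> List[GuidePair]:
    """All opposite-strand guide pairs with 5'-end offset in range.

    ``guides`` must map to one genomic region (one CDS / gene) so that their
    coordinates are comparable.  Each unordered pair appears once, with the
    genomically left guide stored first.
    """
    pairs: List[GuidePair] = []
    for i, a in enumerate(guides):
        for b in guides[i + 1:]:
            if a.strand == b.strand:
                continue
            offset = _pair_offset(a, b)
            if min_offset <= offset <= max_offset:
                left, right = (a, b) if (a.start, a.strand) <= (b.start, b.strand) else (b, a)
                pairs.append(GuidePair(left=left, right=right, offset=offset))
    return pairs


def _splice(genome: SequenceRecord, intervals, strand: str, name: str) -> SequenceRecord:
    """Concatenate exonic intervals 5'->3' into one spliced CDS record."""
    parts = [genome.seq[s:e] for s, e in sorted(intervals)]
    seq = "".join(parts)
    if strand == "-":
        seq = reverse_complement(seq)
    return SequenceRecord(id=name, seq=seq)


def cds_from_bed(
    genome_records: Sequence[SequenceRecord], bed_path: str
) -> List[SequenceRecord]:
    """Spliced CDS records from BED6 intervals, grouped by the name column.

    All intervals sharing a name must lie on one chromosome and strand; they
    are spliced in genomic order and reverse-complemented for minus-strand
    transcripts.
    """
    by_id = {r.id: r for r in genome_records}
    groups: dict = {}
    with open(bed_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"BED6 line with {len(f)} fields: {line!r}")
            chrom, start, end, name, _score, strand = f[:6]
            key = (name, chrom, strand)
            groups.setdefault(key, []).append((int(start), int(end)))
    out = []
    for (name, chrom, strand), ivals in groups.items():
        if chrom not in by_id:
            raise ValueError(f"BED chromosome {chrom!r} not in genome")
        out.append(_splice(by_id[chrom], ivals, strand, name))
    return out


def cds_from_gff3(
    genome_records: Sequence[SequenceRecord], gff3_path: str
) -> List[SequenceRecord]:
    """Spliced CDS records from GFF3 ``CDS`` features grouped by Parent."""
    import gffutils

    db = gffutils.create_db(
        gff3_path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    by_id = {r.id: r for r in genome_records}
    groups: dict = {}
    for feat in db.features_of_type("CDS"):
        parents = feat.attributes.get("Parent", [feat.id or "cds"])
        for parent in parents:
            key = (parent, feat.seqid, feat.strand)
            # GFF3 is 1-based inclusive
            groups.setdefault(key, []).append((feat.start - 1, feat.end))
    out = []
    for (name, chrom, strand), ivals in groups.items():
        if chrom not in by_id:
            raise ValueError(f"GFF3 seqid {chrom!r} not in genome")
        out.append(_splice(by_id[chrom], ivals, strand, name))
    return out


def guides_to_tsv(guides: Iterable[GuideRNA], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("guide\tsource\tstart\tend\tstrand\tprotospacer\tpam\tgc\n")
        for g in guides:
            fh.write(
                f"{g.name}\t{g.source_id}\t{g.start}\t{g.end}\t{g.strand}"
                f"\t{g.protospacer}\t{g.pam}\t{g.gc:.2f}\n"
            )


def guides_to_bed6_rows(
    guides: Iterable[GuideRNA],
) -> List[Tuple[str, int, int, str, int, str]]:
    return [(g.source_id, g.start, g.end, g.name, 0, g.strand) for g in guides]
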