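"""Amplicon read tallies: eligibility, indel window, dsODN tag, HDR edit.

Consumes aligned reads (SAM) plus the reference amplicon and counts, per
the processing rules used throughout this package:

* a read is *eligible* when it covers and matches at least 75% of the
  first 20 bp of the reference amplicon;
* an eligible read is *indel-positive* when its alignment carries at
  least one insertion or deletion whose leftmost reference coordinate
  (after left-normalizing the gap against the reference) falls within
  +/-2 bp of the cut site; indel frequency divides by total reads;
* a read is *tag-positive* when its sequence contains either 15-mer
  center fragment of the double-strand oligo tag (exact, case-insensitive);
* a read is *edit-positive* when every programmed substitution is present
  at its reference position and no indel lies in the cut window.

Interpretation note: "indels without mismatches" is read as counting gap
operations only — substitutions elsewhere in a read do not disqualify it.

Coordinates are 0-based half-open internally; the cut site is an
inter-base offset (between reference positions cut_site-1 and cut_site).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pysam

DSODN_FRAGMENTS = ("gttgtcatatgttaa", "ttaacatatgacaac")
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


class AmpliconError(ValueError):
    pass


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class AmpliconSpec:
    """Reference amplicon, protospacer placement and scoring targets."""

    reference: str
    protospacer: str = ""
    strand: str = "+"
    cut_site: int | None = None  # inter-base offset into the reference
    dsodn_fragments: tuple = DSODN_FRAGMENTS
    desired_edit: dict = field(default_factory=dict)  # ref position (0-based) -> base

    def __post_init__(self) -> None:
        self.reference = self.reference.upper()
        self.protospacer = self.protospacer.upper()
        if self.protospacer:
            fwd = self.reference.count(self.protospacer)
            rev = self.reference.count(revcomp(self.protospacer))
            if fwd + rev != 1:
                raise AmpliconError(
                    f"protospacer must map exactly once into the reference "
                    f"(found {fwd} forward / {rev} reverse)"
                )
            self.strand = "+" if fwd else "-"
            if self.cut_site is None:
                # blunt cut 3 nt upstream of the PAM: between protospacer
                # positions 17 and 18 counting from the PAM-distal end
                if self.strand == "+":
                    start = self.reference.index(self.protospacer)
                    self.cut_site = start + len(self.protospacer) - 3
                else:
                    start = self.reference.index(revcomp(self.protospacer))
                    self.cut_site = start + 3
        if self.cut_site is None:
            raise AmpliconError("cut_site is required when no protospacer is given")
        if not 0 < self.cut_site < len(self.reference):
            raise AmpliconError("cut_site must lie inside the reference")
        a, b = (f.lower() for f in self.dsodn_fragments)
        if revcomp(a) != b:
            raise AmpliconError("dsODN fragments must be reverse complements of each other")
        for pos, base in self.desired_edit.items():
            if not 0 <= int(pos) < len(self.reference):
                raise AmpliconError(f"desired edit position {pos} outside reference")
            if str(base).upper() not in "ACGT":
                raise AmpliconError(f"desired edit base {base!r} not a nucleotide")

    def mirrored(self) -> "AmpliconSpec":
        """The reverse-complement view of the same amplicon (for tests)."""
        n = len(self.reference)
        return AmpliconSpec(
            reference=revcomp(self.reference),
            protospacer=self.protospacer,
            cut_site=n - self.cut_site,
            dsodn_fragments=self.dsodn_fragments,
            desired_edit={
                n - 1 - int(p): revcomp(str(b)) for p, b in self.desired_edit.items()
            },
        )

    def write_fasta(self, path, name: str = "amplicon") -> None:
        with open(path, "w") as fh:
            fh.write(f">{name}\n")
            for i in range(0, len(self.reference), 70):
                fh.write(self.reference[i : i + 70] + "\n")


@dataclass
class IndelSummary:
    total_reads: int
    eligible_reads: int
    indel_reads: int
    tag_reads: int
    edit_reads: int
    denominator: str = "total"  # or "eligible"
    unit: str = "reads"  # "fragments" when mate-aware
    flag: str = ""

    def _den(self) -> int:
        return self.total_reads if self.denominator == "total" else self.eligible_reads

    @property
    def indel_frequency(self) -> float:
        return self.indel_reads / self._den() if self._den() else 0.0

    @property
    def tag_frequency(self) -> float:
        return self.tag_reads / self._den() if self._den() else 0.0

    @property
    def edit_fraction(self) -> float:
        return self.edit_reads / self._den() if self._den() else 0.0


def _left_normalize_deletion(ref: str, start: int, length: int) -> int:
    """Shift a deletion's leftmost reference coordinate as far left as the
    flanking sequence allows (standard gap left-alignment)."""
    while start > 0 and ref[start - 1] == ref[start + length - 1]:
        start -= 1
    return start


def _left_normalize_insertion(ref: str, start: int, inserted: str) -> int:
    while start > 0 and inserted and inserted[-1] == ref[start - 1]:
        inserted = ref[start - 1] + inserted[:-1]
        start -= 1
    return start


def read_gap_positions(read: pysam.AlignedSegment, reference: str) -> list:
    """Leftmost reference coordinates of every gap in the read's alignment.

    Insertions are anchored at the reference position they precede;
    deletions at their first deleted base.  Gaps are left-normalized
    against the reference.
    """
    positions = []
    rpos = read.reference_start
    qpos = 0
    seq = read.query_sequence or ""
    for op, length in read.cigartuples or []:
        if op in (0, 7, 8):  # M, =, X
            rpos += length
            qpos += length
        elif op == 1:  # I
            inserted = seq[qpos : qpos + length]
            positions.append(_left_normalize_insertion(reference, rpos, inserted))
            qpos += length
        elif op == 2:  # D
            positions.append(_left_normalize_deletion(reference, rpos, length))
            rpos += length
        elif op == 3:  # N
            rpos += length
        elif op in (4,):  # S
            qpos += length
        # H/P consume nothing relevant
    return positions


def is_eligible(
    read: pysam.AlignedSegment, spec: AmpliconSpec, min_match: float = 0.75, head: int = 20
) -> bool:
    """Eligibility: >= ``min_match`` of the reference's first ``head``
    positions are covered by the read and match its bases."""
    if read.is_unmapped:
        return False
    needed = math.ceil(min_match * head)
    seq = read.query_sequence or ""
    matches = 0
    for qpos, rpos in read.get_aligned_pairs(matches_only=True):
        if rpos is not None and rpos < head:
            if qpos is not None and seq[qpos].upper() == spec.reference[rpos]:
                matches += 1
        elif rpos is not None and rpos >= head:
            break
    return matches >= needed


def has_indel_in_window(
    read: pysam.AlignedSegment, spec: AmpliconSpec, window: int = 2
) -> bool:
    cut = spec.cut_site
    if cut - window < 0 or cut + window > len(spec.reference):
        raise AmpliconError("indel window extends outside the reference")
    for pos in read_gap_positions(read, spec.reference):
        if cut - window <= pos <= cut + window:
            return True
    return False


def has_tag(read: pysam.AlignedSegment, spec: AmpliconSpec) -> bool:
    seq = (read.query_sequence or "").lower()
    return any(frag.lower() in seq for frag in spec.dsodn_fragments)


def has_edit(read: pysam.AlignedSegment, spec: AmpliconSpec, window: int = 2) -> bool:
    """All programmed substitutions present, with no indel in the window."""
    if not spec.desired_edit:
        return False
    if has_indel_in_window(read, spec, window):
        return False
    seq = read.query_sequence or ""
    found = {}
    for qpos, rpos in read.get_aligned_pairs(matches_only=True):
        if rpos in spec.desired_edit:
            found[rpos] = seq[qpos].upper()
    return all(found.get(int(p)) == str(b).upper() for p, b in spec.desired_edit.items())


def tally_reads(
    reads,
    spec: AmpliconSpec,
    *,
    window: int = 2,
    min_match: float = 0.75,
    denominator: str = "total",
) -> IndelSummary:
    """Tally an iterable of aligned reads against one amplicon.

    When mate information is present, segments sharing a query name are
    counted once as a fragment (positive if any segment is positive);
    otherwise each read counts on its own.
    """
    if denominator not in ("total", "eligible"):
        raise AmpliconError(f"unknown denominator mode {denominator!r}")
    if spec.cut_site - window < 0 or spec.cut_site + window > len(spec.reference):
        raise AmpliconError("indel window extends outside the reference")
    units: dict = {}
    paired_seen = False
    serial = 0
    for read in reads:
        if read.is_unmapped:
            key = f"__unmapped{serial}"
        elif read.is_paired:
            paired_seen = True
            key = read.query_name
        else:
            key = f"__read{serial}:{read.query_name}"
        serial += 1
        rec = units.setdefault(
            key, {"eligible": False, "indel": False, "tag": False, "edit": False}
        )
        if read.is_unmapped:
            continue
        eligible = is_eligible(read, spec, min_match=min_match)
        rec["eligible"] |= eligible
        if eligible:
            rec["indel"] |= has_indel_in_window(read, spec, window=window)
        rec["tag"] |= has_tag(read, spec)
        rec["edit"] |= has_edit(read, spec, window=window)

    total = len(units)
    return IndelSummary(
        total_reads=total,
        eligible_reads=sum(u["eligible"] for u in units.values()),
        indel_reads=sum(u["indel"] for u in units.values()),
        tag_reads=sum(u["tag"] for u in units.values()),
        edit_reads=sum(u["edit"] for u in units.values()),
        denominator=denominator,
        unit="fragments" if paired_seen else "reads",
        flag="" if total else "empty input",
    )


def tally_sam(
    sam_path,
    spec: AmpliconSpec,
    *,
    window: int = 2,
    min_match: float = 0.75,
    denominator: str = "total",
) -> IndelSummary:
    """Tally a SAM file of reads aligned to the amplicon reference."""
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as fh:
        ref_names = set(fh.references)
        reads = []
        for read in fh:
            if not read.is_unmapped and ref_names and read.reference_name not in ref_names:
                raise AmpliconError(f"read {read.query_name} aligned to unknown reference")
            reads.append(read)
    return tally_reads(reads, spec, window=window, min_match=min_match, denominator=denominator)


def simulate_reads(
    spec: AmpliconSpec,
    mix: dict,
    n: int,
    seed: int = 0,
    *,
    out_sam=None,
    substitution_noise: float = 0.0,
    ref_name: str = "amplicon",
) -> tuple:
    """Generate aligned reads with programmed outcomes at the cut site.

    ``mix`` gives proportions for the read classes ``wt``, ``indel``
    (a 2-bp deletion or 1-bp insertion at the cut, 50/50), ``tagged``
    (15-mer tag fragment inserted at the cut) and ``edited`` (the
    programmed substitutions); proportions must sum to 1.  Classes are
    drawn i.i.d. per read, so realized counts are binomial.  Returns
    (records, truth_counts); ``out_sam`` additionally writes a SAM file.
    """
    classes = ("wt", "indel", "tagged", "edited")
    probs = np.array([float(mix.get(c, 0.0)) for c in classes])
    if abs(probs.sum() - 1.0) > 1e-9 or (probs < 0).any():
        raise AmpliconError("mix proportions must be non-negative and sum to 1")
    if any(k not in classes for k in mix):
        raise AmpliconError(f"unknown read classes: {sorted(set(mix) - set(classes))}")
    if "edited" in mix and mix["edited"] > 0 and not spec.desired_edit:
        raise AmpliconError("edited reads requested but spec.desired_edit is empty")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1312]))
    ref = spec.reference
    cut = spec.cut_site
    drawn = rng.choice(len(classes), size=n, p=probs)
    truth = {c: int((drawn == i).sum()) for i, c in enumerate(classes)}

    header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": ref_name, "LN": len(ref)}]}
    records = []
    for i, ci in enumerate(drawn):
        cls = classes[ci]
        if cls == "wt":
            seq, cigar = ref, f"{len(ref)}M"
        elif cls == "indel":
            if rng.uniform() < 0.5 and cut + 2 <= len(ref):
                seq = ref[:cut] + ref[cut + 2 :]
                cigar = f"{cut}M2D{len(ref) - cut - 2}M"
            else:
                ins = "ACGT"[rng.integers(4)]
                seq = ref[:cut] + ins + ref[cut:]
                cigar = f"{cut}M1I{len(ref) - cut}M"
        elif cls == "tagged":
            frag = spec.dsodn_fragments[int(rng.integers(2))].upper()
            seq = ref[:cut] + frag + ref[cut:]
            cigar = f"{cut}M{len(frag)}I{len(ref) - cut}M"
        else:  # edited
            bases = list(ref)
            for pos, b in spec.desired_edit.items():
                bases[int(pos)] = str(b).upper()
            seq, cigar = "".join(bases), f"{len(ref)}M"
        if substitution_noise > 0:
            protected = set(int(p) for p in spec.desired_edit) if cls == "edited" else set()
            bases = list(seq)
            hits = np.nonzero(rng.uniform(size=len(bases)) < substitution_noise)[0]
            for j in hits:
                if cls != "edited" or j not in protected:
                    bases[j] = "ACGT"[(("ACGT".index(bases[j]) + 1 + rng.integers(3)) % 4)]
            seq = "".join(bases)
        a = pysam.AlignedSegment(header=pysam.AlignmentHeader.from_dict(header))
        a.query_name = f"sim{i:06d}_{cls}"
        a.query_sequence = seq
        a.flag = 0
        a.reference_id = 0
        a.reference_start = 0
        a.mapping_quality = 60
        a.cigarstring = cigar
        records.append(a)

    if out_sam is not None:
        with pysam.AlignmentFile(
            str(out_sam), "wh", header=pysam.AlignmentHeader.from_dict(header)
        ) as fh:
            for a in records:
                fh.write(a)
    return records, truth


def mirror_read(read: pysam.AlignedSegment, spec: AmpliconSpec) -> pysam.AlignedSegment:
    """Reverse-complement a read into the mirrored reference frame (tests)."""
    n = len(spec.reference)
    header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": "amplicon", "LN": n}]}
    end = read.reference_end
    a = pysam.AlignedSegment(header=pysam.AlignmentHeader.from_dict(header))
    a.query_name = read.query_name
    a.query_sequence = revcomp(read.query_sequence or "")
    a.flag = 0
    a.reference_id = 0
    a.reference_start = n - end
    a.mapping_quality = read.mapping_quality
    a.cigartuples = list(reversed(read.cigartuples or []))
    return a
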