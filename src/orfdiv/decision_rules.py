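"""Candidate selection, the opposite-strand mirror discard rule, and the
erroneous-start flag.

Synonymous changes in a real gene sit mostly at third codon positions, and
those same nucleotide changes read in an opposite-strand frame often appear
synonymous again. A true gene therefore *mirrors* an apparently constrained
ORF onto the complementary strand. Because bidirectional coding is rare,
a candidate ORF largely contained in a longer opposite-strand candidate is
treated as such an artifact and discarded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from orfdiv.microdiversity import OrfDiversityStats
from orfdiv.orf_model import Orf


@dataclass(frozen=True)
class DecisionConfig:
    """Thresholds for the decision rules.

    * ``candidate_max_ratio`` — pNeg/pS at or below this marks a coding
      candidate (default 1.0).
    * ``overprint_max_ratio`` — candidates overlapping another candidate in
      a different frame may run up to this ratio (default 1.5): selection
      on the ancestral gene constrains an overprinted gene's substitutions
      and inflates its pNeg/pS.
    * ``start_fold`` / ``first_nt`` — an ORF whose first ``first_nt`` bases
      show a pNeg/pS at least ``start_fold`` times the whole-ORF value is
      flagged as having a suspect (likely downstream) true start.
    * ``containment_frac`` — fraction of the smaller ORF that must be
      covered by an opposite-strand candidate for the mirror discard.
    * ``min_first50_snps`` — evidence floor for the start rule.
    """

    candidate_max_ratio: float = 1.0
    overprint_max_ratio: float = 1.5
    start_fold: float = 2.0
    first_nt: int = 50
    containment_frac: float = 0.9
    min_first50_snps: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.candidate_max_ratio <= self.overprint_max_ratio:
            raise ValueError("need 0 < candidate_max_ratio <= overprint_max_ratio")
        if self.start_fold <= 1:
            raise ValueError("start_fold must be > 1")
        if not 0 < self.containment_frac <= 1:
            raise ValueError("containment_frac must be in (0, 1]")


def _footprint(orf: Orf, genome_length: int) -> set[int]:
    if orf.wraps_origin:
        return set(range(orf.start, genome_length)) | set(range(orf.end))
    return set(range(orf.start, orf.end))


def overlap_nt(a: Orf, b: Orf, genome_length: int) -> int:
    """Number of genome positions covered by both ORFs (strand-agnostic)."""
    return len(_footprint(a, genome_length) & _footprint(b, genome_length))


def flag_candidates(
    stats: Sequence[OrfDiversityStats],
    genome_length: int,
    cfg: DecisionConfig = DecisionConfig(),
) -> list[OrfDiversityStats]:
    """Assign ``candidate`` and ``overprint_candidate`` flags in place.

    candidate: pNeg/pS <= candidate_max_ratio with sufficient data.
    overprint_candidate: ratio in (candidate_max_ratio, overprint_max_ratio]
    and overlapping a candidate ORF in a different frame or strand — the
    regime of overprinted genes.
    """
    for s in stats:
        s.flags.discard("candidate")
        s.flags.discard("overprint_candidate")
        if "insufficient_data" in s.flags or math.isnan(s.pneg_ps):
            continue
        if s.pneg_ps <= cfg.candidate_max_ratio:
            s.flags.add("candidate")
    candidates = [s for s in stats if "candidate" in s.flags]
    for s in stats:
        if "candidate" in s.flags or "insufficient_data" in s.flags or math.isnan(s.pneg_ps):
            continue
        if not cfg.candidate_max_ratio < s.pneg_ps <= cfg.overprint_max_ratio:
            continue
        for c in candidates:
            different_frame = c.orf.strand != s.orf.strand or c.orf.frame != s.orf.frame
            if different_frame and overlap_nt(s.orf, c.orf, genome_length) > 0:
                s.flags.add("overprint_candidate")
                break
    return list(stats)


def _mirror_priority(s: OrfDiversityStats) -> tuple:
    # longer first; then lower ratio; then + strand; start as final determinism key
    return (-s.orf.length_nt, s.pneg_ps, 0 if s.orf.strand == "+" else 1, s.orf.start)


def mirror_filter(
    stats: Sequence[OrfDiversityStats],
    genome_length: int,
    cfg: DecisionConfig = DecisionConfig(),
) -> list[tuple[str, str]]:
    """Discard candidate ORFs shadowed by longer opposite-strand candidates.

    A candidate B is ``mirror_discarded`` when a surviving candidate A on
    the opposite strand covers at least ``containment_frac`` of B and is
    strictly longer (equal lengths with mutual containment are broken by
    lower pNeg/pS, then by the plus strand surviving). Discarded ORFs lose
    candidate status. Returns (shadowed, shadowing) id pairs. Idempotent:
    survivors are decided longest-first, so re-running changes nothing.
    """
    candidates = sorted(
        (s for s in stats if "candidate" in s.flags or "mirror_discarded" in s.flags),
        key=_mirror_priority,
    )
    survivors: list[OrfDiversityStats] = []
    relations: list[tuple[str, str]] = []
    for s in candidates:
        shadow_of = None
        for a in survivors:
            if a.orf.strand == s.orf.strand:
                continue
            if a.orf.length_nt < s.orf.length_nt:
                continue
            cov = overlap_nt(a.orf, s.orf, genome_length)
            if cov < cfg.containment_frac * s.orf.length_nt:
                continue
            if a.orf.length_nt > s.orf.length_nt:
                shadow_of = a
                break
            # equal length, mutual containment: earlier priority survives
            mutual = cov >= cfg.containment_frac * a.orf.length_nt
            if mutual and _mirror_priority(a) < _mirror_priority(s):
                shadow_of = a
                break
        if shadow_of is None:
            s.flags.discard("mirror_discarded")
            s.flags.add("candidate")
            survivors.append(s)
        else:
            s.flags.add("mirror_discarded")
            s.flags.discard("candidate")
            relations.append((s.orf_id, shadow_of.orf_id))
    return relations


def flag_suspect_start(
    stats: Sequence[OrfDiversityStats],
    cfg: DecisionConfig = DecisionConfig(),
) -> list[OrfDiversityStats]:
    """Flag ORFs whose first stretch looks noncoding relative to the whole.

    ``suspect_start`` is set when the pNeg/pS of the first ``first_nt``
    bases is at least ``start_fold`` times the whole-ORF ratio, both ratios
    are finite and defined, the whole-ORF ratio is positive, and at least
    ``min_first50_snps`` informative effects support the first stretch.
    The true start codon then likely lies downstream of the annotated one.
    """
    for s in stats:
        s.flags.discard("suspect_start")
        whole, first = s.pneg_ps, s.first50_pneg_ps
        if not (math.isfinite(whole) and math.isfinite(first)):
            continue
        if whole <= 0 or s.n_snps_first50 < cfg.min_first50_snps:
            continue
        if first >= cfg.start_fold * whole:
            s.flags.add("suspect_start")
    return list(stats)
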