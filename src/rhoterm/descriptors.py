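"""The 13 rut-site descriptors, YC-dimer motif chains and pause-site scan.

The descriptors summarize a terminator zone's C>G bubbles: the longest
bubble's length (L1), the cumulated length of all bubbles, their density
along the sequence, the longest bubble's area (S1), the cumulated area, the
area density, the longest bubble's maximal %C, maximal and average %C − %G,
the counts of YC-dimer chains of multiplicity 1/2/3 inside the longest
bubble, and the whole-sequence YC-dimer density.  Y is the pyrimidine set
{C, T}; chained dimers must be 9–13 bases apart.

Structural work places 5'-YC dimers at the primary RNA-binding site of the
Rho hexamer, which is why their count inside the best bubble is a proxy for
rut-site quality.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum

from .bubble_scan import (
    DESCRIPTOR_WINDOW_NT,
    STEP_NT,
    Bubble,
    detect_bubbles,
    window_profile,
)
from .errors import TooShortError
from .sequence_model import SequenceRecord

#: Allowed gap (bases between consecutive dimers) in a YC chain.
YC_GAP_RANGE = (9, 13)

#: Elemental RNA-polymerase pause consensus, 16 nt, one degenerate position.
#: Lowercase marks weakly conserved positions (relevant to core-only matching).
PAUSE_CONSENSUS = "GGcataatTG(C/T)GGCcg"
_PAUSE_TEMPLATE = "GGcataatTG*GGCcg"  # '*' marks the degenerate C/T slot
_PAUSE_LEN = 16
_PAUSE_DEGENERATE_POS = 10


class GapConvention(str, Enum):
    """How the 9–13 base chain distance is measured between dimers."""

    GAP = "gap"  # end of first dimer -> start of next (default)
    START_TO_START = "start_to_start"


@dataclass(frozen=True)
class MotifChain:
    """A chain of YC dimers with qualifying inter-motif gaps."""

    positions: tuple[int, ...]
    order: int

    def __post_init__(self) -> None:
        assert self.order == len(self.positions)


@dataclass(frozen=True)
class PauseHit:
    offset: int
    matched: str
    variant: str  # C or T at the degenerate position


@dataclass(frozen=True)
class DescriptorSet:
    """The 13 rut-site descriptors for one analyzed sequence of length L_t."""

    L1_longest_bubble_len: int
    cum_len_all_bubbles: int
    density_len: float
    S1_longest_bubble_area: float
    cum_area_all_bubbles: float
    density_area: float
    max_pctC_longest: float
    max_diff_longest: float
    avg_diff_longest: float
    yc1_longest: int
    yc2_longest: int
    yc3_longest: int
    yc_density: float
    window_size: int = DESCRIPTOR_WINDOW_NT
    step: int = STEP_NT
    L_t: int = 0
    n_bubbles: int = 0
    upstream_bubble_offset: int | None = None  # QC: 5'-most bubble start

    FIELDS = (
        "L1_longest_bubble_len", "cum_len_all_bubbles", "density_len",
        "S1_longest_bubble_area", "cum_area_all_bubbles", "density_area",
        "max_pctC_longest", "max_diff_longest", "avg_diff_longest",
        "yc1_longest", "yc2_longest", "yc3_longest", "yc_density",
    )

    def as_row(self, gene: str) -> dict:
        row = {"gene": gene}
        row.update({f: getattr(self, f) for f in self.FIELDS})
        row.update(
            window_size=self.window_size, step=self.step, L_t=self.L_t,
            n_bubbles=self.n_bubbles,
            upstream_bubble_offset=(
                None
                if self.upstream_bubble_offset is None
                else self.upstream_bubble_offset + 1
            ),
        )
        return row


def yc_dimer_positions(seq: str) -> list[int]:
    """Start offsets of every YC dimer (Y in {C,T}); overlaps all counted."""
    return [
        i
        for i in range(len(seq) - 1)
        if seq[i] in "CT" and seq[i + 1] == "C"
    ]


def count_yc_motifs(
    seq: str,
    gap_range: tuple[int, int] = YC_GAP_RANGE,
    convention: GapConvention = GapConvention.GAP,
) -> tuple[int, int, int, list[int]]:
    """Count YC dimers and their 2- and 3-chains with 9–13 base spacing.

    Returns ``(yc1, yc2, yc3, positions)``: yc1 counts all dimers
    (overlaps included); yc2 and yc3 count occurrences of 2- and 3-dimer
    chains by distinct start offset — a dimer starts at most one counted
    chain of each order however many partners qualify, which keeps
    yc3 <= yc2 <= yc1 on every sequence (pair counting would violate it
    wherever dimers overlap, e.g. inside CCC runs).  Under the default
    ``gap`` convention the spacing is the number of bases between the end
    of one dimer and the start of the next; ``start_to_start`` measures
    between dimer start offsets instead.
    """
    positions = yc_dimer_positions(seq)
    lo, hi = gap_range
    offset = 2 if convention is GapConvention.GAP else 0

    def qualifies(p: int, q: int) -> bool:
        return lo <= q - (p + offset) <= hi

    succ: dict[int, list[int]] = {
        p: [q for q in positions if q > p and qualifies(p, q)] for p in positions
    }
    chain2 = {p for p, qs in succ.items() if qs}
    chain3 = {p for p, qs in succ.items() if any(succ[q] for q in qs)}
    return len(positions), len(chain2), len(chain3), positions


def longest_bubble(bubbles: list[Bubble]) -> Bubble | None:
    """The bubble maximizing length; ties go to larger area, then most 5'."""
    if not bubbles:
        return None
    return max(bubbles, key=lambda b: (b.length, b.area, -b.start))


def compute_descriptors(
    seq: SequenceRecord | str,
    window_size: int = DESCRIPTOR_WINDOW_NT,
    step: int = STEP_NT,
    gap_convention: GapConvention = GapConvention.GAP,
    threshold: float = 0.0,
    extent: str = "footprint",
) -> DescriptorSet:
    """Compute all 13 descriptors for one terminator-zone sequence.

    Bubble-scoped descriptors are 0 when no window has %C > %G.  YC chain
    counts (yc1/2/3) are taken inside the longest bubble's footprint; the
    YC density is counted over the whole sequence and normalized by L_t.
    ``threshold``/``extent`` are passed through to the bubble detector
    (defaults: bare %C > %G, full window footprints).
    """
    residues = seq.residues if isinstance(seq, SequenceRecord) else seq
    L_t = len(residues)
    if L_t < window_size:
        raise TooShortError(f"sequence length {L_t} < window size {window_size}")
    profile = window_profile(residues, window_size, step)
    bubbles = detect_bubbles(profile, threshold=threshold, extent=extent)
    yc_full, _, _, _ = count_yc_motifs(residues)
    best = longest_bubble(bubbles)
    if best is None:
        return DescriptorSet(
            0, 0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0, 0, 0,
            yc_density=yc_full / L_t,
            window_size=window_size, step=step, L_t=L_t, n_bubbles=0,
        )
    yc1, yc2, yc3, _ = count_yc_motifs(
        residues[best.start : best.end], convention=gap_convention
    )
    cum_len = sum(b.length for b in bubbles)
    cum_area = sum(b.area for b in bubbles)
    return DescriptorSet(
        L1_longest_bubble_len=best.length,
        cum_len_all_bubbles=cum_len,
        density_len=cum_len / L_t,
        S1_longest_bubble_area=best.area,
        cum_area_all_bubbles=cum_area,
        density_area=cum_area / L_t,
        max_pctC_longest=best.max_pctC,
        max_diff_longest=best.max_diff,
        avg_diff_longest=best.avg_diff,
        yc1_longest=yc1,
        yc2_longest=yc2,
        yc3_longest=yc3,
        yc_density=yc_full / L_t,
        window_size=window_size,
        step=step,
        L_t=L_t,
        n_bubbles=len(bubbles),
        upstream_bubble_offset=min(b.start for b in bubbles),
    )


def _pause_regex(policy: str) -> re.Pattern[str]:
    if policy not in ("strict", "core"):
        raise ValueError(f"unknown pause-match policy {policy!r}")
    chars = []
    for c in _PAUSE_TEMPLATE:
        if c == "*":
            chars.append("[CT]")
        elif c.isupper():  # strongly conserved position
            chars.append(c)
        else:  # weakly conserved: literal under strict, free under core
            chars.append(c.upper() if policy == "strict" else ".")
    return re.compile(f"(?=({''.join(chars)}))")


def scan_pause_sites(
    seq: SequenceRecord | str, policy: str = "strict"
) -> list[PauseHit]:
    """Scan for the elemental pause consensus GGcataatTG(C/T)GGCcg.

    ``policy='strict'`` requires every position literal (with C or T at the
    degenerate slot); ``policy='core'`` constrains only the strongly
    conserved (uppercase-printed) positions.  Overlapping hits are all
    reported.
    """
    residues = seq.residues if isinstance(seq, SequenceRecord) else seq
    hits = []
    for m in _pause_regex(policy).finditer(residues):
        matched = m.group(1)
        hits.append(
            PauseHit(
                offset=m.start(),
                matched=matched,
                variant=matched[_PAUSE_DEGENERATE_POS],
            )
        )
    return hits
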