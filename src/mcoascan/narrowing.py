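"""IBD-interval narrowing from haplotype-discordant flanking markers.

The disease haplotype shared by affected horses cannot extend across a site
whose genotypes contradict haplotype sharing, so each flank of the mapped
interval is trimmed to one base past the innermost contradicting marker.
The excluded segment includes the discordant marker's own position; the
narrowed interval starts at the next base.

The candidate span (pattern-concordant variants) anchors the scan: markers
below the lowest candidate belong to the 5' flank, markers above the highest
candidate to the 3' flank.  Discordant markers *between* candidates cannot be
used for trimming (the candidate span is positively established) and are
reported separately for audit.  With no candidates, each marker is assigned
to the nearer edge.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .intervals import GenomicInterval


class NarrowingError(ValueError):
    """No concordant IBD core remains after trimming."""


@dataclass(frozen=True)
class NarrowingResult:
    original: GenomicInterval
    narrowed: GenomicInterval
    excluded_5prime_bp: int
    excluded_3prime_bp: int
    boundary_marker_5prime: int | None  # innermost 5' discordant position
    boundary_marker_3prime: int | None
    interior_discordants: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        total = self.excluded_5prime_bp + self.excluded_3prime_bp + self.narrowed.length()
        assert total == self.original.length(), "length bookkeeping violated"


def narrow_interval(
    region: GenomicInterval,
    candidate_positions: Iterable[int],
    discordant_positions: Iterable[int],
) -> NarrowingResult:
    """Trim ``region`` using discordant flank markers anchored on candidates.

    All positions must lie inside ``region``.  Raises :class:`NarrowingError`
    when the trimmed boundaries cross (discordance spans the whole region).
    """
    candidates = sorted(set(candidate_positions))
    discordant = sorted(set(discordant_positions))
    for pos in candidates + discordant:
        if not region.contains(pos):
            raise NarrowingError(f"marker position {pos} outside region {region}")

    interior: list[int] = []
    if candidates:
        lo, hi = candidates[0], candidates[-1]
        flank5 = [p for p in discordant if p < lo]
        flank3 = [p for p in discordant if p > hi]
        interior = [p for p in discordant if lo <= p <= hi]
    else:
        flank5 = [p for p in discordant if p - region.start <= region.end - p]
        flank3 = [p for p in discordant if p - region.start > region.end - p]

    marker5 = max(flank5) if flank5 else None
    marker3 = min(flank3) if flank3 else None
    new_start = marker5 + 1 if marker5 is not None else region.start
    new_end = marker3 - 1 if marker3 is not None else region.end
    if new_start > new_end:
        raise NarrowingError("no IBD core remains: discordant markers span the region")

    narrowed = GenomicInterval(region.chrom, new_start, new_end)
    return NarrowingResult(
        original=region,
        narrowed=narrowed,
        excluded_5prime_bp=new_start - region.start,
        excluded_3prime_bp=region.end - new_end,
        boundary_marker_5prime=marker5,
        boundary_marker_3prime=marker3,
        interior_discordants=tuple(interior),
    )


def write_narrowing_report(
    path: str | Path,
    result: NarrowingResult,
    responsible_samples: Mapping[int, Sequence[str]] | None = None,
) -> None:
    """JSON report of original/narrowed coordinates and per-flank exclusions."""
    payload = {
        "original": {"chrom": result.original.chrom, "start": result.original.start,
                     "end": result.original.end, "length_bp": result.original.length()},
        "narrowed": {"chrom": result.narrowed.chrom, "start": result.narrowed.start,
                     "end": result.narrowed.end, "length_bp": result.narrowed.length()},
        "excluded_5prime_bp": result.excluded_5prime_bp,
        "excluded_3prime_bp": result.excluded_3prime_bp,
        "excluded_total_bp": result.excluded_5prime_bp + result.excluded_3prime_bp,
        "boundary_marker_5prime": result.boundary_marker_5prime,
        "boundary_marker_3prime": result.boundary_marker_3prime,
        "interior_discordants": list(result.interior_discordants),
        "responsible_samples": {
            str(pos): list(samples)
            for pos, samples in (responsible_samples or {}).items()
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


__all__ = ["NarrowingResult", "NarrowingError", "narrow_interval",
           "write_narrowing_report"]
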