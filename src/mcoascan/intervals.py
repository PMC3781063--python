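"""1-based inclusive genomic intervals.

All coordinates inside the package are 1-based and inclusive on both ends,
matching the convention used for the MCOA identity-by-descent interval
(ECA6:73,640,494-73,848,154).  BED files are 0-based half-open; conversion
happens only at the file boundary (:meth:`GenomicInterval.from_bed_fields`
and :meth:`GenomicInterval.to_bed_fields`).
"""

from __future__ import annotations

from dataclasses import dataclass


class IntervalError(ValueError):
    """Raised for malformed genomic intervals."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    chrom: str
    start: int  # 1-based, inclusive
    end: int    # 1-based, inclusive

    def __post_init__(self) -> None:
        if self.start < 1:
            raise IntervalError(f"interval start must be >= 1, got {self.start}")
        if self.start > self.end:
            raise IntervalError(
                f"interval start {self.start} exceeds end {self.end} on {self.chrom}"
            )

    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int, chrom: str | None = None) -> bool:
        if chrom is not None and chrom != self.chrom:
            return False
        return self.start <= pos <= self.end

    def contains_interval(self, other: "GenomicInterval") -> bool:
        return (
            other.chrom == self.chrom
            and other.start >= self.start
            and other.end <= self.end
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            other.chrom == self.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    # --- BED boundary conversion ---------------------------------------
    def to_bed_fields(self) -> tuple[str, int, int]:
        """(chrom, 0-based start, half-open end)."""
        return self.chrom, self.start - 1, self.end

    @classmethod
    def from_bed_fields(cls, chrom: str, bed_start: int, bed_end: int) -> "GenomicInterval":
        return cls(chrom, bed_start + 1, bed_end)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"
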