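"""Core genomic data model.

All coordinates are 0-based, half-open (BED convention). GFF3 input
(1-based, closed) is converted on read by :mod:`padscan.io`. Strand is
carried on intervals and genes but ignored by all overlap computations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

VALID_STRANDS = {"+", "-", "."}
VALID_BIOTYPES = {"protein_coding", "TE_gene", "pseudogene"}


@dataclass
class Interval:
    """A genomic interval on a named chromosome, 0-based half-open."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start in {self.chrom}:{self.start}-{self.end}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class GenomeLayout:
    """Chromosome geometry plus centromere/pericentromere annotation.

    ``chromosomes`` is an ordered list of ``(name, length_bp)``.
    ``centromere`` and ``pericentromere`` map chromosome name to a
    half-open interval; an interval with ``start == end`` means the
    chromosome has no (peri)centromere. The centromere must lie inside
    the pericentromere on every chromosome.
    """

    chromosomes: list[tuple[str, int]]
    centromere: dict[str, tuple[int, int]] = field(default_factory=dict)
    pericentromere: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [name for name, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        lengths = dict(self.chromosomes)
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"non-positive length for chromosome {name}")
        for table, label in ((self.centromere, "centromere"),
                             (self.pericentromere, "pericentromere")):
            for chrom, (s, e) in table.items():
                if chrom not in lengths:
                    raise ValueError(f"{label} on unknown chromosome {chrom}")
                if not (0 <= s <= e <= lengths[chrom]):
                    raise ValueError(
                        f"{label} [{s}, {e}) outside chromosome {chrom}"
                    )
        for chrom, (cs, ce) in self.centromere.items():
            ps, pe = self.pericentromere.get(chrom, (cs, cs))
            if cs < ce and not (ps <= cs and ce <= pe):
                raise ValueError(
                    f"centromere not contained in pericentromere on {chrom}"
                )

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.chromosomes]

    def length(self, chrom: str) -> int:
        for name, length in self.chromosomes:
            if name == chrom:
                return length
        raise KeyError(chrom)

    @property
    def total_bp(self) -> int:
        return sum(length for _, length in self.chromosomes)

    def peri(self, chrom: str) -> tuple[int, int]:
        """Pericentromere interval; empty (0, 0) when none is annotated."""
        return self.pericentromere.get(chrom, (0, 0))

    def arms(self, chrom: str) -> list[tuple[int, int]]:
        """Chromosome-arm intervals: everything outside the pericentromere."""
        length = self.length(chrom)
        ps, pe = self.peri(chrom)
        if ps >= pe:
            return [(0, length)]
        out = []
        if ps > 0:
            out.append((0, ps))
        if pe < length:
            out.append((pe, length))
        return out

    @property
    def total_arm_bp(self) -> int:
        return sum(e - s for chrom in self.names for s, e in self.arms(chrom))

    def validate_interval(self, iv: Interval) -> None:
        if iv.chrom not in dict(self.chromosomes):
            raise ValueError(f"interval on unknown chromosome {iv.chrom}")
        if iv.end > self.length(iv.chrom):
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
                f"length {self.length(iv.chrom)}"
            )


@dataclass
class GeneAnnotation:
    """A gene with its transcribed-region span, biotype and expression level."""

    gene_id: str
    interval: Interval
    strand: str = "."
    biotype: str = "protein_coding"
    expression: float = 0.0

    def __post_init__(self) -> None:
        if self.biotype not in VALID_BIOTYPES:
            raise ValueError(f"unknown biotype {self.biotype!r}")
        if self.expression < 0:
            raise ValueError("expression must be nonnegative")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")


@dataclass
class FragmentSet:
    """Aligned fragments from one pull-down sample (antibody x replicate)."""

    label: str
    fragments: list[Interval]

    @property
    def total(self) -> int:
        return len(self.fragments)
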