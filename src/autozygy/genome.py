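"""Genome build: ordered autosome names and lengths.

A :class:`GenomeBuild` is the single coordinate frame shared by every
stage of the pipeline.  All internal coordinates are 0-based half-open;
VCF output is 1-based, BED output 0-based half-open, per their standards.
Only autosomes are modelled: hemizygous sex chromosomes break the
diploid heterozygosity model underlying ROH calling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

# GRCh37 (hg19) autosome lengths, the coordinate frame used throughout.
GRCH37_AUTOSOMES: tuple[tuple[str, int], ...] = (
    ("chr1", 249250621), ("chr2", 243199373), ("chr3", 198022430),
    ("chr4", 191154276), ("chr5", 180915260), ("chr6", 171115067),
    ("chr7", 159138663), ("chr8", 146364022), ("chr9", 141213431),
    ("chr10", 135534747), ("chr11", 135006516), ("chr12", 133851895),
    ("chr13", 115169878), ("chr14", 107349540), ("chr15", 102531392),
    ("chr16", 90354753), ("chr17", 81195210), ("chr18", 78077248),
    ("chr19", 59128983), ("chr20", 63025520), ("chr21", 48129895),
    ("chr22", 51304566),
)


@dataclass(frozen=True)
class GenomeBuild:
    """Ordered list of (chromosome name, length in bp)."""

    chromosomes: tuple[tuple[str, int], ...]
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        names = [n for n, _ in self.chromosomes]
        if len(names) != len(set(names)):
            raise ValueError("chromosome names must be unique")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
        object.__setattr__(self, "_index", {n: l for n, l in self.chromosomes})

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    @property
    def lengths(self) -> list[int]:
        return [l for _, l in self.chromosomes]

    @property
    def total_length(self) -> int:
        return sum(self.lengths)

    def length_of(self, chrom: str) -> int:
        return self._index[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._index

    def __len__(self) -> int:
        return len(self.chromosomes)

    def to_chrom_sizes(self, path) -> None:
        """Write a two-column chrom-sizes TSV (name, length)."""
        with open(path, "w") as fh:
            for name, length in self.chromosomes:
                fh.write(f"{name}\t{length}\n")

    @classmethod
    def from_chrom_sizes(cls, path) -> "GenomeBuild":
        chroms = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                name, length = line.split("\t")[:2]
                chroms.append((name, int(length)))
        if not chroms:
            raise ValueError(f"no chromosomes in {path}")
        return cls(tuple(chroms))


def grch37_autosomes() -> GenomeBuild:
    """The default genome build: the 22 GRCh37 autosomes (~2.88 Gbp)."""
    return GenomeBuild(GRCH37_AUTOSOMES)
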