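"""Locus schemas for the seven folate-pathway polymorphisms.

Each locus is biallelic in the coupling sense (the TYMS 28bp repeat is
treated as 2R/3R), with three genotype classes ordered as
(major homozygote, heterozygote, minor homozygote).
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class LocusSchema:
    """A biallelic locus with its three genotype-class labels.

    ``genotype_labels`` is the ordered triple
    (major homozygote, heterozygote, minor homozygote); ``alleles`` is the
    (major, minor) allele-name pair used when planting haplotype couplings.
    """

    locus_name: str
    genotype_labels: tuple[str, str, str]
    alleles: tuple[str, str] = field(default=("0", "1"))

    def __post_init__(self) -> None:
        if len(self.genotype_labels) != 3:
            raise ValueError(
                f"{self.locus_name}: exactly 3 genotype labels required, "
                f"got {len(self.genotype_labels)}"
            )
        if len(set(self.genotype_labels)) != 3:
            raise ValueError(f"{self.locus_name}: genotype labels must be distinct")

    def class_index(self, call: str) -> int:
        """Index of ``call`` in the (major-hom, het, minor-hom) ordering."""
        try:
            return self.genotype_labels.index(call)
        except ValueError:
            raise ValueError(
                f"unknown genotype label {call!r} for locus {self.locus_name} "
                f"(expected one of {self.genotype_labels})"
            ) from None

    def minor_allele_count(self, call: str) -> int:
        return self.class_index(call)


# The seven canonical loci, labelled as printed in the study tables.
CANONICAL_LOCI: tuple[LocusSchema, ...] = (
    LocusSchema("MTHFR677", ("CC", "CT", "TT"), ("C", "T")),
    LocusSchema("MTHFR1298", ("AA", "AC", "CC"), ("A", "C")),
    LocusSchema("MTRR66", ("AA", "AG", "GG"), ("A", "G")),
    LocusSchema("MTR2756", ("AA", "AG", "GG"), ("A", "G")),
    LocusSchema("RFC1_80", ("GG", "GA", "AA"), ("G", "A")),
    LocusSchema("TYMS_28bp", ("2R/2R", "2R/3R", "3R/3R"), ("2R", "3R")),
    LocusSchema("TYMS_6bp", ("6bp +/+", "6bp +/-", "6bp -/-"), ("+", "-")),
)

CANONICAL_BY_NAME: dict[str, LocusSchema] = {s.locus_name: s for s in CANONICAL_LOCI}


def noise_locus_schema(index: int) -> LocusSchema:
    """Schema for the ``index``-th uninformative filler locus."""
    name = f"NOISE{index:02d}"
    return LocusSchema(name, ("aa", "ab", "bb"), ("a", "b"))
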