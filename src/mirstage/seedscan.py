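"""Canonical seed-site detection in 3'UTR sequences.

The seed is miRNA nucleotides 2-8 (1-based, from the 5' end). A UTR site
is an exact Watson-Crick reverse complement of part of the seed, read on
the UTR sense strand, in one of four canonical classes:

* 8mer      — reverse complement of positions 2-8, followed by A
* 7mer-m8   — reverse complement of positions 2-8
* 7mer-A1   — reverse complement of positions 2-7, followed by A
* 6mer      — reverse complement of positions 2-7

Overlapping matches are reported once, at the most specific class. G:U
wobble pairing is not allowed. This module is an optional sequence-level
extension: it emits the same interaction tables the network module reads.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

from .enums import SiteType
from .errors import ValidationError
from .network import InteractionTable

__all__ = ["SeedSite", "find_seed_sites", "scan_fasta", "sites_to_edges"]

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


def _clean_rna(seq: str, what: str) -> str:
    """Uppercase, T->U, validate alphabet."""
    clean = str(seq).strip().upper().replace("T", "U")
    bad = set(clean) - set("ACGU")
    if bad:
        raise ValidationError(f"invalid characters in {what}: {sorted(bad)}")
    return clean


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


@dataclass(frozen=True)
class SeedSite:
    """One seed-match site; 0-based half-open interval on the UTR sense strand."""

    mirna_id: str
    gene: str
    start: int
    end: int
    site_type: SiteType

    def __post_init__(self) -> None:
        if self.end - self.start != self.site_type.span:
            raise ValidationError(
                f"interval length {self.end - self.start} does not match "
                f"{self.site_type.name}"
            )
        if self.start < 0:
            raise ValidationError("site start must be non-negative")


def find_seed_sites(
    mirna_sequence: str,
    utr_sequence: str,
    mirna_id: str = "",
    gene: str = "",
) -> list[SeedSite]:
    """Scan one UTR (sense strand, 5'->3') for seed sites of one miRNA.

    Each occurrence of the 6mer core (reverse complement of seed positions
    2-7) is classified upward: a matching m8 position upgrades it toward
    7mer-m8, a downstream A toward 7mer-A1, and both together make an 8mer.
    Only the most specific class is reported per occurrence.
    """
    mirna = _clean_rna(mirna_sequence, "miRNA sequence")
    if len(mirna) < 8:
        raise ValidationError(f"miRNA sequence too short ({len(mirna)} nt, need >= 8)")
    utr = _clean_rna(utr_sequence, "UTR sequence")

    core = _revcomp(mirna[1:7])          # matches seed positions 2-7
    m8_match = _COMPLEMENT[mirna[7]]     # base pairing seed position 8

    sites: list[SeedSite] = []
    pos = utr.find(core)
    while pos != -1:
        has_m8 = pos > 0 and utr[pos - 1] == m8_match
        has_a1 = pos + 6 < len(utr) and utr[pos + 6] == "A"
        if has_m8 and has_a1:
            site = SeedSite(mirna_id, gene, pos - 1, pos + 7, SiteType.SITE_8MER)
        elif has_m8:
            site = SeedSite(mirna_id, gene, pos - 1, pos + 6, SiteType.SITE_7MER_M8)
        elif has_a1:
            site = SeedSite(mirna_id, gene, pos, pos + 7, SiteType.SITE_7MER_A1)
        else:
            site = SeedSite(mirna_id, gene, pos, pos + 6, SiteType.SITE_6MER)
        sites.append(site)
        pos = utr.find(core, pos + 1)
    return sites


def scan_fasta(mirna_fasta: str | Path, utr_fasta: str | Path) -> list[SeedSite]:
    """All seed sites between a FASTA of mature miRNAs and a FASTA of 3'UTRs.

    miRNA record ids are taken as miRNA names; UTR record ids as gene symbols.
    """
    mirnas = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(mirna_fasta), "fasta")]
    utrs = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(utr_fasta), "fasta")]
    if not mirnas:
        raise ValidationError(f"no records in miRNA FASTA {mirna_fasta}")
    if not utrs:
        raise ValidationError(f"no records in UTR FASTA {utr_fasta}")
    sites: list[SeedSite] = []
    for mirna_id, mseq in mirnas:
        for gene, useq in utrs:
            sites.extend(find_seed_sites(mseq, useq, mirna_id=mirna_id, gene=gene.upper()))
    return sites


def sites_to_edges(
    sites: list[SeedSite], min_type: SiteType = SiteType.SITE_7MER_A1
) -> InteractionTable:
    """Collapse sites to one edge per (miRNA, gene) with >= min_type specificity."""
    rows = [
        (s.mirna_id, s.gene, "seedscan")
        for s in sites
        if s.site_type >= min_type
    ]
    if not rows:
        return InteractionTable(edges={})
    return InteractionTable.from_rows(rows)
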