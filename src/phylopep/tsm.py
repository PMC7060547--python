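"""Taxon-to-spectrum-match (TSM) counting.

A PSM assigns one MS/MS spectrum to one peptide sequence; because the same
tryptic peptide occurs in many proteomes, each PSM fans out to every taxon
carrying a matching protein.  A TSM is a spectrum attributed to a taxon via
any of its peptides — the taxon-level analogue of a protein's spectral count
and the quantitative unit every downstream fit consumes.  This module
validates PSMs, maps peptides to taxa, counts TSMs / peptides / specific
peptides per taxon, and collates the counts from the directly assigned taxa
up to the seven canonical ranks.
"""

from __future__ import annotations

import logging
import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from phylopep.taxonomy import CANONICAL_RANKS, TaxonomyTree

logger = logging.getLogger(__name__)

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: pseudo-rank for counts at the directly assigned (most resolved) taxa
ASSIGNED_RANK = "assigned"

#: synthetic bin for taxa that cannot be placed in the taxonomy
UNPLACED = -1


@dataclass(frozen=True)
class PsmRecord:
    """One peptide-to-spectrum match with its search-engine expectation."""

    spectrum_id: str
    peptide: str
    expectation: float
    accessions: tuple[str, ...]

    def __post_init__(self):
        if not self.peptide or not set(self.peptide) <= AMINO_ACIDS:
            raise ValueError(
                f"peptide must be a non-empty uppercase amino-acid string, "
                f"got {self.peptide!r}"
            )
        if not self.expectation > 0:
            raise ValueError(f"expectation must be > 0, got {self.expectation}")
        if not self.accessions:
            raise ValueError("accessions must be non-empty")
        object.__setattr__(self, "accessions", tuple(self.accessions))


def validate_psms(records: Iterable[PsmRecord], threshold: float = 0.1
                  ) -> list[PsmRecord]:
    """Keep PSMs with expectation strictly below `threshold` (default 0.1).

    Several surviving PSMs may share one spectrum id; all are retained.
    """
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    return [r for r in records if r.expectation < threshold]


def exclude_contaminants(records: Iterable[PsmRecord],
                         contaminant_accessions: set[str]) -> list[PsmRecord]:
    """Strip contaminant accessions; drop records left with none.

    A record matching both a contaminant (keratin, trypsin, ...) and a sample
    protein keeps its sample accessions.
    """
    if not contaminant_accessions:
        return list(records)
    out = []
    for r in records:
        kept = tuple(a for a in r.accessions if a not in contaminant_accessions)
        if kept:
            out.append(r if kept == r.accessions else
                       PsmRecord(r.spectrum_id, r.peptide, r.expectation, kept))
    return out


def map_peptides_to_taxa(records: Iterable[PsmRecord],
                         acc2tax: Mapping[str, Iterable[int]]
                         ) -> dict[str, frozenset[int]]:
    """Union the taxa of every accession of every record carrying a peptide.

    Accessions absent from the mapping are skipped with a tally (mapping
    tables are always incomplete); peptides whose accessions are all unmapped
    are omitted.  An entirely unmapped input yields an empty map with a
    warning.
    """
    taxa: dict[str, set[int]] = {}
    unmapped = 0
    total = 0
    for r in records:
        bucket = taxa.setdefault(r.peptide, set())
        for acc in r.accessions:
            total += 1
            hit = acc2tax.get(acc)
            if hit is None:
                unmapped += 1
            else:
                bucket.update([hit] if isinstance(hit, int) else hit)
    if unmapped:
        logger.info("map_peptides_to_taxa: %d/%d accessions unmapped",
                    unmapped, total)
    if total and unmapped == total:
        warnings.warn("no accession could be mapped to a taxon", stacklevel=2)
    return {pep: frozenset(t) for pep, t in taxa.items() if t}


@dataclass
class TsmTable:
    """Per-(rank, taxon) spectrum / peptide counts.

    ``df`` is long-format with columns rank, taxid, tsm, psm, peptides,
    specific_peptides, specific_tsms.  The pseudo-rank ``assigned`` holds the
    counts at the directly assigned taxa; the seven canonical ranks hold the
    deduplicated rollups.
    """

    df: pd.DataFrame
    unplaced_taxa: frozenset[int] = field(default_factory=frozenset)

    def counts(self, rank: str, taxid: int) -> pd.Series:
        sub = self.df[(self.df["rank"] == rank) & (self.df["taxid"] == taxid)]
        if sub.empty:
            return pd.Series(
                0, index=["tsm", "psm", "peptides",
                          "specific_peptides", "specific_tsms"])
        return sub.iloc[0][["tsm", "psm", "peptides",
                            "specific_peptides", "specific_tsms"]]

    def tsm(self, rank: str, taxid: int) -> int:
        return int(self.counts(rank, taxid)["tsm"])

    def write_tsv(self, path, tree: TaxonomyTree | None = None) -> None:
        out = self.df.copy()
        if tree is not None:
            out.insert(2, "name", [
                tree.name(t) if t in tree else "unplaced"
                for t in out["taxid"]])
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "TsmTable":
        df = pd.read_csv(path, sep="\t")
        cols = ["rank", "taxid", "tsm", "psm", "peptides",
                "specific_peptides", "specific_tsms"]
        return cls(df[cols])


def _rollup(taxa: frozenset[int], rank: str, tree: TaxonomyTree,
            unplaced: set[int]) -> frozenset[int]:
    """Map a set of assigned taxa to their rank-level groups.

    Taxa missing from the tree land in the synthetic UNPLACED bin; taxa whose
    lineage lacks the rank are dropped (LCA-style convention).
    """
    out = set()
    for t in taxa:
        if t not in tree:
            unplaced.add(t)
            out.add(UNPLACED)
            continue
        anc = tree.lineage_at_level(t, rank)
        if anc is not None:
            out.add(anc)
    return frozenset(out)


def count_tsms(records: Iterable[PsmRecord],
               pep2tax: Mapping[str, frozenset[int]],
               tree: TaxonomyTree,
               ranks: tuple[str, ...] = CANONICAL_RANKS) -> TsmTable:
    """Count TSMs, PSMs, peptides and specific peptides per taxon and rank.

    At each level a spectrum contributes at most once to a taxon's TSM count,
    however many of its peptides map there.  A peptide is *specific* to a
    taxon at a rank when its full taxon set rolls up to that taxon alone; a
    spectrum is a *specific TSM* when every one of its matched peptides is
    specific to the taxon.
    """
    records = list(records)
    # distinct (spectrum, peptide) pairs with a mapped peptide
    pairs = {(r.spectrum_id, r.peptide) for r in records
             if r.peptide in pep2tax}
    spec_peps: dict[str, set[str]] = {}
    for s, p in pairs:
        spec_peps.setdefault(s, set()).add(p)

    unplaced: set[int] = set()
    levels: dict[str, dict[str, frozenset[int]]] = {
        ASSIGNED_RANK: {p: pep2tax[p] for p in {p for _, p in pairs}}
    }
    for rank in ranks:
        levels[rank] = {
            p: _rollup(pep2tax[p], rank, tree, unplaced)
            for p in levels[ASSIGNED_RANK]
        }

    rows = []
    for rank, groups_of in levels.items():
        pep_members: dict[int, set[str]] = {}
        for pep, groups in groups_of.items():
            for g in groups:
                pep_members.setdefault(g, set()).add(pep)
        for g, peps in sorted(pep_members.items()):
            g_pairs = {(s, p) for s, p in pairs if p in peps}
            g_spectra = {s for s, _ in g_pairs}
            specific = {p for p in peps if groups_of[p] == frozenset({g})}
            spec_spectra = {
                s for s in g_spectra if spec_peps[s] <= specific
            }
            rows.append({
                "rank": rank, "taxid": g,
                "tsm": len(g_spectra), "psm": len(g_pairs),
                "peptides": len(peps),
                "specific_peptides": len(specific),
                "specific_tsms": len(spec_spectra),
            })
    df = pd.DataFrame(
        rows, columns=["rank", "taxid", "tsm", "psm", "peptides",
                       "specific_peptides", "specific_tsms"])
    if unplaced:
        logger.warning("count_tsms: %d taxa absent from the taxonomy were "
                       "binned as unplaced", len(unplaced))
    return TsmTable(df, frozenset(unplaced))


def tsm_profile(table: TsmTable, rank: str) -> list[tuple[int, int]]:
    """Taxa at `rank` with tsm > 0, sorted by descending count.

    Equal counts order by ascending taxon id so the profile is reproducible.
    """
    sub = table.df[(table.df["rank"] == rank) & (table.df["tsm"] > 0)]
    sub = sub.sort_values(["tsm", "taxid"], ascending=[False, True])
    return list(zip(sub["taxid"].tolist(), sub["tsm"].tolist()))


# -- I/O helpers -----------------------------------------------------------

def read_psms(path) -> list[PsmRecord]:
    """Read the PSM TSV schema: spectrum_id, peptide, expectation, accessions
    (semicolon-separated)."""
    df = pd.read_csv(path, sep="\t", dtype={"spectrum_id": str})
    return [
        PsmRecord(row.spectrum_id, row.peptide, float(row.expectation),
                  tuple(str(row.accessions).split(";")))
        for row in df.itertuples()
    ]


def read_acc2tax(path) -> dict[str, frozenset[int]]:
    """Read a two-column accession -> taxid TSV; repeated accessions form a
    multimap."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["accession", "taxid"], comment="#")
    out: dict[str, set[int]] = {}
    for row in df.itertuples():
        out.setdefault(str(row.accession), set()).add(int(row.taxid))
    return {a: frozenset(t) for a, t in out.items()}


def read_contaminants(source) -> set[str]:
    """Accession list, one per line; cRAP-style FASTA headers accepted."""
    if isinstance(source, (str, os.PathLike)) and os.path.exists(source):
        with open(source) as fh:
            lines = fh.read().splitlines()
    elif isinstance(source, str):
        lines = source.splitlines()
    else:
        lines = list(source)
    out = set()
    for line in lines:
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            out.add(line[1:].split()[0])
        else:
            out.add(line.split()[0])
    return out
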