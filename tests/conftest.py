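"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from phylopep.taxonomy import CANONICAL_RANKS, TaxonomyTree, load_taxonomy

NODES_DMP = """\
1\t|\t1\t|\tno rank\t|
2\t|\t1\t|\tsuperkingdom\t|
5\t|\t2\t|\tphylum\t|
6\t|\t5\t|\tclass\t|
7\t|\t6\t|\torder\t|
10\t|\t7\t|\tfamily\t|
20\t|\t10\t|\tgenus\t|
30\t|\t20\t|\tspecies\t|
31\t|\t20\t|\tspecies\t|
40\t|\t30\t|\tno rank\t|
41\t|\t31\t|\tno rank\t|
21\t|\t10\t|\tgenus\t|
32\t|\t21\t|\tspecies\t|
33\t|\t20\t|\tspecies\t|
"""

NAMES_DMP = """\
1\t|\troot\t|\t\t|\tscientific name\t|
2\t|\tBacteria\t|\t\t|\tscientific name\t|
5\t|\tProteobacteria\t|\t\t|\tscientific name\t|
6\t|\tGammaproteobacteria\t|\t\t|\tscientific name\t|
7\t|\tEnterobacterales\t|\t\t|\tscientific name\t|
10\t|\tEnterobacteriaceae\t|\t\t|\tscientific name\t|
20\t|\tShigella\t|\t\t|\tscientific name\t|
30\t|\tShigella flexneri\t|\t\t|\tscientific name\t|
31\t|\tShigella sonnei\t|\t\t|\tscientific name\t|
40\t|\tS. flexneri 2a\t|\t\t|\tsynonym\t|
21\t|\tSalmonella\t|\t\t|\tscientific name\t|
32\t|\tSalmonella bongori\t|\t\t|\tscientific name\t|
"""


@pytest.fixture(scope="session")
def toy_tree() -> TaxonomyTree:
    """Hand-built 13-node taxonomy with a full canonical lineage."""
    return load_taxonomy(NODES_DMP, NAMES_DMP)


def random_taxonomy(rng: np.random.Generator, n_species: int = 6
                    ) -> tuple[TaxonomyTree, list[int]]:
    """Random taxonomy with complete canonical lineages; returns the tree and
    its species-level leaf ids."""
    from phylopep.taxonomy import TaxNode

    nodes = {1: TaxNode(1, 1, "no rank", "root")}
    nxt = 2
    parents = [1]
    for rank in reversed(CANONICAL_RANKS):  # superkingdom .. species
        new = []
        for p in parents:
            for _ in range(int(rng.integers(1, 3)) if rank != "species" else
                           max(1, n_species // max(1, len(parents)))):
                nodes[nxt] = TaxNode(nxt, p, rank, f"taxon{nxt}")
                new.append(nxt)
                nxt += 1
        parents = new
    return TaxonomyTree(nodes, 1), parents


def brute_force_tsm_counts(records, pep2tax, tree, rank):
    """Independent enumeration oracle for TSM counting at one rank.

    Loops spectra x peptides x taxa directly, computing every count from
    first principles.
    """
    def groups_of(taxon):
        if rank == "assigned":
            return {taxon}
        if taxon not in tree:
            return {-1}
        anc = tree.lineage_at_level(taxon, rank)
        return {anc} if anc is not None else set()

    mapped = [r for r in records if r.peptide in pep2tax]
    all_groups = set()
    for r in mapped:
        for t in pep2tax[r.peptide]:
            all_groups |= groups_of(t)

    out = {}
    for g in all_groups:
        spectra, pairs, peptides = set(), set(), set()
        for r in mapped:
            in_g = any(g in groups_of(t) for t in pep2tax[r.peptide])
            if in_g:
                spectra.add(r.spectrum_id)
                pairs.add((r.spectrum_id, r.peptide))
                peptides.add(r.peptide)
        specific = set()
        for p in peptides:
            rolled = set()
            for t in pep2tax[p]:
                rolled |= groups_of(t)
            if rolled == {g}:
                specific.add(p)
        spec_spectra = set()
        for s in spectra:
            peps_of_s = {r.peptide for r in mapped if r.spectrum_id == s}
            if peps_of_s and peps_of_s <= specific:
                spec_spectra.add(s)
        out[g] = {
            "tsm": len(spectra), "psm": len(pairs),
            "peptides": len(peptides), "specific_peptides": len(specific),
            "specific_tsms": len(spec_spectra),
        }
    return out
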