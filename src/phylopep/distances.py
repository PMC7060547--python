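"""Pan-domain phylogenetic distance construction.

Two build paths feed the signature fit with a taxon-pair distance matrix:

* cophenetic (patristic) extraction from a newick tree with branch lengths;
* the marker-gene route: per-taxon homolog selection for a panel of
  hyper-conserved COGs, concatenation into an aligned "supervector" against a
  pre-aligned reference alignment, conservation masking, and an all-pairs
  percent-identity matrix (PIM) whose complement, d = 1 - PI/100, is the
  distance.

The alignment and homology-search steps themselves are delegated to external
tools; this module consumes their standard tabular/FASTA outputs and owns the
validation, masking, PIM and bookkeeping logic.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

GAP_CHARS = frozenset("-.")

#: the 31 hyper-conserved, cross-superkingdom marker COGs
DEFAULT_COGS: tuple[str, ...] = (
    "COG0012", "COG0016", "COG0048", "COG0049", "COG0052", "COG0080",
    "COG0081", "COG0087", "COG0091", "COG0092", "COG0093", "COG0094",
    "COG0096", "COG0097", "COG0098", "COG0099", "COG0100", "COG0102",
    "COG0103", "COG0172", "COG0184", "COG0186", "COG0197", "COG0200",
    "COG0201", "COG0202", "COG0256", "COG0495", "COG0522", "COG0525",
    "COG0533",
)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances over an ordered taxon panel.

    PIM-derived and simulated distances live on [0, 1]; raw patristic
    distances may exceed 1 and can be brought onto [0, 1] with
    :meth:`normalized`.
    """

    taxa: list
    d: np.ndarray

    def __post_init__(self):
        self.taxa = list(self.taxa)
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError(f"distance matrix shape {self.d.shape} does not "
                             f"match {n} taxa")
        if len(set(self.taxa)) != n:
            raise ValueError("duplicate taxa in panel")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("distances must be finite")
        if np.any(self.d < 0):
            raise ValueError("distances must be non-negative")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("diagonal must be zero")
        self.d = (self.d + self.d.T) / 2.0
        np.fill_diagonal(self.d, 0.0)
        self._index = {t: i for i, t in enumerate(self.taxa)}

    def __contains__(self, taxon) -> bool:
        return taxon in self._index

    def index(self, taxon) -> int:
        try:
            return self._index[taxon]
        except KeyError:
            raise KeyError(f"taxon {taxon!r} not in distance matrix") from None

    def get(self, a, b) -> float:
        return float(self.d[self.index(a), self.index(b)])

    def row(self, taxon) -> np.ndarray:
        return self.d[self.index(taxon)]

    def submatrix(self, taxa: Sequence) -> "DistanceMatrix":
        idx = [self.index(t) for t in taxa]
        return DistanceMatrix(list(taxa), self.d[np.ix_(idx, idx)])

    def normalized(self) -> "DistanceMatrix":
        """Rescale so the largest distance is 1 (identity if already <= 1)."""
        m = self.d.max()
        return DistanceMatrix(self.taxa, self.d / m if m > 1 else self.d.copy())

    # -- I/O ---------------------------------------------------------------

    def to_long_frame(self) -> pd.DataFrame:
        rows = [
            (self.taxa[i], self.taxa[j], self.d[i, j])
            for i in range(len(self.taxa)) for j in range(i + 1, len(self.taxa))
        ]
        return pd.DataFrame(rows, columns=["taxid_a", "taxid_b", "distance"])

    def write_tsv(self, path, long: bool = True) -> None:
        if long:
            self.to_long_frame().to_csv(path, sep="\t", index=False)
        else:
            pd.DataFrame(self.d, index=self.taxa, columns=self.taxa).to_csv(
                path, sep="\t")

    @classmethod
    def read_long_tsv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t")
        taxa = sorted(set(df["taxid_a"]) | set(df["taxid_b"]))
        idx = {t: i for i, t in enumerate(taxa)}
        d = np.zeros((len(taxa), len(taxa)))
        for row in df.itertuples():
            i, j = idx[row.taxid_a], idx[row.taxid_b]
            d[i, j] = d[j, i] = row.distance
        return cls(taxa, d)

    @classmethod
    def read_wide_tsv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.columns), df.to_numpy(dtype=float))


def cophenetic_distances(newick: str, normalize: bool = False) -> DistanceMatrix:
    """Patristic (leaf-to-leaf branch-length sum) distances from a newick tree.

    Raw branch-length units by default; ``normalize=True`` rescales onto
    [0, 1].  Missing branch lengths and duplicate leaf labels are errors.
    """
    tree = dendropy.Tree.get(data=newick, schema="newick")
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(leaves)) != len(leaves):
        raise ValueError("duplicate leaf labels in newick tree")
    if len(leaves) == 1:
        return DistanceMatrix(leaves, np.zeros((1, 1)))
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            node = edge.head_node
            label = (node.taxon.label if node.taxon else "internal node")
            raise ValueError(f"missing branch length at {label}")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    dm = DistanceMatrix([t.label for t in taxa], d)
    return dm.normalized() if normalize else dm


# -- homolog selection -----------------------------------------------------

@dataclass(frozen=True)
class HomologHit:
    """One tabular homology-search hit for a marker-gene query."""

    cog: str
    subject: str
    evalue: float
    identity: float          # percent, [0, 100]
    coverage: float          # fraction, [0, 1]

    def __post_init__(self):
        if self.evalue < 0:
            raise ValueError("e-value must be >= 0")
        if not 0 <= self.identity <= 100:
            raise ValueError("identity must be in [0, 100]")
        if not 0 <= self.coverage <= 1:
            raise ValueError("coverage must be in [0, 1]")


def validate_hit(hit: HomologHit) -> bool:
    """Strict acceptance: e-value < 0.001, identity > 45 %, coverage > 94 %."""
    return hit.evalue < 0.001 and hit.identity > 45.0 and hit.coverage > 0.94


def read_homology_hits(source, query_lengths: Mapping[str, int] | None = None
                       ) -> dict[str, list[HomologHit]]:
    """Parse 12-column tabular search output (BLAST outfmt-6 dialect).

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend sstart
    send evalue bitscore [coverage].  When the 13th coverage column is absent
    it is computed as alignment length / query length from `query_lengths`.
    The query id is taken as the COG id.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        try:
            with open(source) as fh:
                text = fh.read()
        except (OSError, ValueError):
            text = source
    hits: dict[str, list[HomologHit]] = {}
    for line in io.StringIO(text):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        cog, subject = f[0], f[1]
        identity, length = float(f[2]), int(f[3])
        evalue = float(f[10])
        if len(f) > 12:
            coverage = float(f[12])
        else:
            if query_lengths is None or cog not in query_lengths:
                raise ValueError(
                    f"no coverage column and no query length for {cog}")
            coverage = min(1.0, length / query_lengths[cog])
        hits.setdefault(cog, []).append(
            HomologHit(cog, subject, evalue, identity, coverage))
    return hits


@dataclass
class Supervector:
    """Per-COG aligned blocks for one taxon, concatenable to one row of the
    reference multiple alignment (8310 positions for the bundled 31-COG
    reference convention)."""

    taxon: object
    blocks: dict[str, str]
    missing: frozenset[str] = field(default_factory=frozenset)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.blocks.values())

    def concat(self, cog_order: Iterable[str] | None = None) -> str:
        order = list(cog_order) if cog_order is not None else sorted(self.blocks)
        return "".join(self.blocks[c] for c in order)


def select_cog_sequences(taxid, cog_ids: Sequence[str],
                         hits_by_cog: Mapping[str, list[HomologHit]],
                         sequences: Mapping[str, str],
                         fallback_reference: Supervector,
                         ) -> tuple[dict[str, str], frozenset[str]]:
    """Pick the best validated hit per COG; fall back to the reference.

    Best = lowest e-value, ties broken by highest identity (then subject
    accession, for determinism).  COGs with no validated hit take the
    reference sequence and are flagged missing.
    """
    chosen: dict[str, str] = {}
    missing: set[str] = set()
    for cog in cog_ids:
        valid = [h for h in hits_by_cog.get(cog, []) if validate_hit(h)]
        if valid:
            best = min(valid, key=lambda h: (h.evalue, -h.identity, h.subject))
            chosen[cog] = sequences[best.subject]
        else:
            chosen[cog] = fallback_reference.blocks[cog]
            missing.add(cog)
    return chosen, frozenset(missing)


def exclude_high_missing(taxa: Sequence, missing_counts: Mapping,
                         limit: int = 10) -> list:
    """Retain taxa with at most `limit` missing COGs (strictly more than
    `limit` excluded)."""
    kept = [t for t in taxa if missing_counts.get(t, 0) <= limit]
    if taxa and not kept:
        warnings.warn("all taxa excluded by the missing-COG limit",
                      stacklevel=2)
    return kept


def dedup_identical_cog_sets(cog_sets: Mapping[object, Mapping[str, str]]
                             ) -> tuple[list, dict]:
    """Group taxa by their exact per-COG sequence sets.

    One representative (smallest taxon id under default ordering) is kept per
    group; the inheritance map sends every member to its representative so
    distances computed for the representative apply to the whole group.
    """
    groups: dict[tuple, list] = {}
    for taxon, blocks in cog_sets.items():
        key = tuple(sorted(blocks.items()))
        groups.setdefault(key, []).append(taxon)
    representatives, inherit = [], {}
    for members in groups.values():
        rep = min(members)
        representatives.append(rep)
        for m in members:
            inherit[m] = rep
    return sorted(representatives), inherit


# -- masking and PIM -------------------------------------------------------

def _column_conserved(column: Sequence[str], min_fraction: float) -> bool:
    """Modal non-gap residue held by strictly more than `min_fraction` of all
    sequences in the block; gaps never disqualify a column by themselves."""
    counts: dict[str, int] = {}
    for ch in column:
        if ch not in GAP_CHARS:
            counts[ch] = counts.get(ch, 0) + 1
    if not counts:
        return False
    return max(counts.values()) > min_fraction * len(column)


def conservation_mask(alignment: Sequence[str], min_fraction: float = 0.5,
                      max_nonconserved_run: int = 8, min_block: int = 2
                      ) -> np.ndarray:
    """Boolean column mask for one superkingdom's aligned block.

    A column is conserved when its modal (non-gap) residue is held by
    strictly more than `min_fraction` of the block's sequences.  Runs of
    non-conserved columns longer than `max_nonconserved_run` split the
    alignment into blocks; each block is trimmed to its first and last
    conserved column and kept whole (internal short non-conserved runs
    included) when it spans at least `min_block` columns.
    """
    if not alignment:
        return np.zeros(0, dtype=bool)
    L = len(alignment[0])
    if any(len(s) != L for s in alignment):
        raise ValueError("ragged alignment")
    conserved = np.array(
        [_column_conserved([s[i] for s in alignment], min_fraction)
         for i in range(L)], dtype=bool)

    mask = np.zeros(L, dtype=bool)
    # region boundaries: long non-conserved runs
    regions: list[tuple[int, int]] = []
    start = 0
    run = 0
    for i in range(L + 1):
        bad = i < L and not conserved[i]
        if bad:
            run += 1
        else:
            if run > max_nonconserved_run:
                regions.append((start, i - run))
                start = i
            run = 0
    if run > max_nonconserved_run:
        regions.append((start, L - run))
        start = L
    regions.append((start, L))

    for lo, hi in regions:
        idx = np.flatnonzero(conserved[lo:hi]) + lo
        if idx.size == 0:
            continue
        first, last = int(idx[0]), int(idx[-1])
        if last - first + 1 >= min_block:
            mask[first:last + 1] = True
    return mask


def union_masks(masks: Sequence[np.ndarray]) -> np.ndarray:
    """Column kept iff kept by any input mask (e.g. the three superkingdom
    masks)."""
    if not masks:
        raise ValueError("need at least one mask")
    lengths = {len(m) for m in masks}
    if len(lengths) != 1:
        raise ValueError(f"mask length mismatch: {sorted(lengths)}")
    out = np.zeros(lengths.pop(), dtype=bool)
    for m in masks:
        out |= np.asarray(m, dtype=bool)
    return out


def apply_mask(sequence: str, mask: np.ndarray) -> str:
    if len(sequence) != len(mask):
        raise ValueError("sequence / mask length mismatch")
    return "".join(ch for ch, keep in zip(sequence, mask) if keep)


def percent_identity(a: str, b: str) -> float:
    """Percent identity over columns where neither sequence has a gap.

    Returns 0 when no comparable column exists.
    """
    if len(a) != len(b):
        raise ValueError("aligned sequences must have equal length")
    comparable = ident = 0
    for x, y in zip(a, b):
        if x in GAP_CHARS or y in GAP_CHARS:
            continue
        comparable += 1
        if x == y:
            ident += 1
    return 100.0 * ident / comparable if comparable else 0.0


def pim_to_distances(taxa: Sequence, supervectors: Sequence[str]
                     ) -> DistanceMatrix:
    """All-pairs distances d = 1 - PI/100 from aligned, masked supervectors."""
    if len(taxa) != len(supervectors):
        raise ValueError("taxa / supervector count mismatch")
    lengths = {len(s) for s in supervectors}
    if len(lengths) > 1:
        raise ValueError("supervectors must share one aligned length")
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pi = percent_identity(supervectors[i], supervectors[j])
            d[i, j] = d[j, i] = 1.0 - pi / 100.0
    return DistanceMatrix(taxa, d)
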