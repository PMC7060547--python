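# Methods

## The signature model

An organism REF present in a sample at TSM-scale abundance `N_REF` projects
shared-peptide spectral counts onto every taxon *i* in the search database.
The expected number of taxon-to-spectrum matches of *i* due to REF is
modelled as

```
y_{i,REF} = N_REF · ( A_REF · exp(−x_{i,REF}/a_REF)
                    + (1 − A_REF) · exp(−x_{i,REF}/b_REF) )
```

where `x_{i,REF} ∈ [0, 1]` is the phylogenetic distance between *i* and REF.
The two exponential terms capture the empirically bilinear (in log space)
decay of shared-peptide counts: a fast component (`a`, dominated by
near-identical strains and species) and a slow component (`b`, the long tail
of deep homology). `A` splits the signal between them and depends on the
depth of the MS/MS acquisition, so it must stay adjustable per dataset.
At `x = 0` the model returns exactly `N`; it is strictly decreasing in `x`.

A community is the superposition of its members' signatures:
`y_i = Σ_k y_{i,REF_k}`. Each reference's own position receives its full
`N_k` plus the other references' leakage; there is no self-exclusion.

### Assumptions

- TSM counts are driven by phylogenetic distance alone; database density,
  genome quality and protein-abundance structure enter only through the
  fitted coefficients.
- One distance scale serves all organisms: distances are fractional
  dissimilarities `d = 1 − PI/100` from a percent-identity matrix over
  concatenated, masked marker genes (the decay constants 0.013/0.082 are
  only meaningful on this [0, 1] axis; this identity→distance transform is
  this package's normative convention).
- Counts enter the objective unweighted (plain sum of squared errors); a
  variance-stabilising weighting is deliberately not applied by default.

## The fit

`SignatureMixtureModel.fit()` minimises `Σ_i (y_i − Σ_k y_{i,k})²` with
L-BFGS-B under box constraints, with analytic gradients. Parameters and
defaults, per reference:

| parameter | default | bounds | unit |
|---|---|---|---|
| `N` | observed TSM count of the reference | `[0, 5·N₀]` | spectra |
| `A` | 0.45 | ±0.05 | – |
| `a` | 0.013 | ±0.001 | distance |
| `b` | 0.082 | ±0.001 | distance |

During the search each parameter is divided by its characteristic scale
(`A₀`, `a₀`, `b₀`, and 100 for `N` — the 1/100 factor is assigned to `N`,
the only parameter otherwise unscaled), so the single termination tolerance
0.01 applies uniformly. The start point is always the defaults (or an
explicit `start`); there is no random initialisation, so the fit is
deterministic given identical inputs. A reference that is itself unobserved
(count 0, e.g. a pure sample fitted with two candidate references) is seeded
from the panel maximum so its `N` bound is not degenerate at zero.

Diagnostics: nearly collinear reference signatures (references closer than
the distance resolution) trigger a condition-number warning, since the split
of `N` between them is then unidentifiable; `bse` reports linearised
Gauss–Newton standard errors of the `N_k` with the decay coefficients held
fixed — approximate, and optimistic when a bound is active.

Relative biomasses are `100 · N_k / Σ_j N_j`; they are invariant to common
rescaling of the `N_k` and sum to 100 by construction.

## TSM counting conventions

- A PSM is valid when its search-engine expectation is strictly below 0.1;
  several PSMs may share one spectrum.
- A spectrum contributes at most one TSM to a taxon, however many of its
  peptides map there; PSM counts are distinct (spectrum, peptide) pairs;
  peptide counts are distinct sequences. Peptide identity is the bare
  sequence (modifications ignored for taxa mapping).
- Rollup to the seven canonical ranks deduplicates spectra and peptides at
  every rank. A peptide is *specific* to a taxon at a rank when its full
  taxon set rolls up to that taxon alone; taxa whose lineage lacks the rank
  are dropped from the rolled set before the test (LCA-style convention),
  and taxa missing from the taxonomy are binned as "unplaced". A spectrum
  is a specific TSM only when *every* one of its matched peptides is
  specific to the taxon — the stricter of the two defensible readings.
- Contaminant accessions are stripped per record; a record is dropped only
  when nothing else remains. Unmapped accessions are tallied, never fatal.

## Distance construction

- **Newick route**: patristic distances (sum of branch lengths on the
  leaf-to-leaf path), raw by default, optionally rescaled to [0, 1].
- **Marker-gene route**: for each taxon and each of the 31 cross-superkingdom
  COGs, the best homology hit (lowest e-value, ties to highest identity) is
  accepted when e-value < 0.001, identity > 45 % and coverage > 94 % — all
  strict; otherwise the reference sequence substitutes and the COG is
  flagged missing. Taxa with more than 10 missing COGs are excluded from the
  distance build; the later fit-panel filter is stricter (*fewer than* 10)
  and both boundaries are implemented exactly as stated. Taxa with
  byte-identical COG sets share one representative and inherit its
  distances.
- **Masking** ("gblocks-like", this package's normative reimplementation of
  a four-parameter rule): a column is conserved when its modal non-gap
  residue is held by strictly more than 50 % of the block's sequences; runs
  of more than 8 consecutive non-conserved columns split the alignment into
  blocks; blocks are trimmed to their first/last conserved column and kept
  whole when they span at least 2 columns. Gaps never disqualify a column
  by themselves. The final mask is the union of the three per-superkingdom
  masks. Percent identity uses gap-free columns only (both-present
  convention) and returns 0 when no column is comparable.
- Tree-based smoothing of the PIM distances (ML/NJ/UPGMA) is deliberately
  not applied.

## The simulator

`random_distance_panel` draws a random coalescent-style ultrametric tree
(random pair merges at increasing exponential heights), scales the largest
leaf-to-leaf distance to the requested spread (default max 0.5, covering the
range over which the signature has appreciable mass) and clips small
off-diagonals up to the spread minimum. References are chosen by
farthest-point selection so their signatures are distinguishable — the
well-separated regime the deconvolution is designed for; degenerate panels
are exercised separately via the collinearity warning. The fit itself never
assumes ultrametricity.

TSM profiles are the mixture expectations, optionally with Poisson noise
(spectral counts are event counts; the default) or negative-binomial
overdispersion (`var = μ + φμ²`, default φ = 0.1). The dilution-series
generator reproduces the standard two-organism design — ratios 1:0, 1:0.1,
1:0.2, 1:0.5, 1:1, 0.5:1, 0.2:1, 0.1:1, 0:1 — scaling each sample's
abundances to a fixed TSM total (default 3000, a typical single-run PSM
yield). `synthetic_peptidome` emulates the generative layer beneath:
per-species peptide sets whose pairwise sharing probability decays with
distance (bi-exponential by default), sampled into PSM records so the
counting stage can be tested end to end.

What the simulator does **not** emulate: peptide detectability and
ionisation efficiency, spectrum-level ambiguity (several peptides per
spectrum), database incompleteness, chromatographic structure, or
organism-specific proteome sizes. Passing recovery tests therefore
demonstrate correctness of the estimator under its own statistical
assumptions, not field performance on real acquisitions.

## Problem sizes and numerical choices

Simulation-based checks use panels of 50–60 taxa, 3000-TSM totals, 25 seeds
for the nine-ratio series and 100 seeds for the 50/50 replicate-spread
check — sizes at which the recovery metrics are stable to well under the
margins being asserted, while the whole suite runs in seconds. Termination
tolerance 0.01 on the scaled objective (the optimiser's own relative-change
criterion); all randomness flows through `numpy.random.default_rng` seeded
per run; ties (equal profile counts, equal node distances, equal e-values)
break deterministically as documented on each function.

## Known limitations

- Abundances are TSM-scale, i.e. proportional to detectable proteome signal;
  converting to cell counts or volumes requires the external metadata the
  `quantify` helpers consume (genome sizes, cell volumes), with all the
  roughness those proxies imply (the community-standard volume-proxy column
  intentionally does not sum to 100 % unless renormalised).
- The narrow boxes around `a`, `b`, `A` encode the empirical stability of
  those coefficients across acquisitions; a dataset with a very different
  depth profile would need wider bounds, at the cost of identifiability.
- Standard errors are linearised and conditional on the decay coefficients.
- References must be specified; there is no automatic discovery of which
  organisms are present.
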