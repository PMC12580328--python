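# Methods

This note documents the models, conventions and numerical choices behind
`oligophos`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Mass calculus

All masses are monoisotopic, computed from a single pinned element table
(H 1.0078250319, C 12, N 14.0030740052, O 15.9949146221, P 30.97376151,
S 31.97207069, Na 22.98976928, Al 26.98153853, Fe 55.93493633 Da).
Residue masses are derived from elemental formulas under this table, so
every printed offset traces back to atomic masses. m/z arithmetic uses
the proton mass (1.00727646 Da); neutral-molecule hydrogen substitutions
use the hydrogen *atom* mass — conflating the two shifts metal-adduct
offsets by ~0.5–1.5 mDa per substitution, which matters at the 5 mDa
matching scale.

A modification hypothesis is a tuple (n_phos, n_fe, n_al, n_na, n_ox)
with neutral offset

    Δm = n_phos·79.9663 + n_fe·(m_Fe − 3 m_H) + n_al·(m_Al − 3 m_H)
         + n_na·(m_Na − m_H) + n_ox·m_O .

Trivalent metals are modelled as a metal atom replacing three hydrogens
of the neutral species, numerically identical to a cation-for-protons
exchange to well below 0.1 mDa. The constraint **n_phos ≥ 2·(n_fe +
n_al)** encodes that a chain must be at least a pyrophosphate to chelate
each trivalent metal; it is enforced by the type and overridable only by
constructing hypotheses directly. The default enumeration (chains 0–6,
≤2 metals, ≤3 oxidations, no Na) yields 104 hypotheses and reproduces
the eight characteristic open-search offsets (79.9666 … 585.6209 Da) to
≤0.5 mDa each, with no two hypotheses within 3 mDa of any of those
classes. Observed deltas are matched at a default tolerance of 0.01 Da
(open-search offsets are reported to 3–4 decimals); ties break by
parsimony (fewest components, then shortest chain). Offsets in the
shipped open-search list that the space does not explain (e.g. 184.0552,
98.0492, 390.788) deliberately report *no match* rather than a forced
fit.

## Digestion

Trypsin cleaves C-terminal of K/R except before P. Peptides carry
1-based inclusive coordinates; the N-terminal Met is retained (no
clipping variants). Search-space filtering (length 7–50, mass
500–5,000 Da) is a separate step so the unfiltered digest remains
inspectable. Properties verified: 0-missed peptides tile the parent;
every k-missed peptide is the concatenation of k+1 adjacent 0-missed
peptides; exact agreement with an O(n²) brute-force enumerator and with
an independent regex-based implementation.

## Fragments and localization

Ion conventions: b = prefix residues + proton; y = suffix + water +
proton; c = b + NH₃; z is the z-dot radical (y − NH₃ + H). Fragments
spanning a modified site carry the site's full composition delta; metal
adducts are treated as **non-dissociating** (retained on every spanning
fragment), consistent with the survival of intact Fe³⁺/Al³⁺ adducts
under low-energy collisional fragmentation; this retention policy is an
assumption and is configurable at the composition level. Neutral losses
(HPO₃ 79.9663, H₃PO₄ 97.9769) are generated only from phosphorylated
fragments, at most two loss events per ion — deeper loss ladders explode
the annotation search space without adding localization power.

Annotation matches each theoretical ion to the nearest peak within a ppm
tolerance (default 10 ppm; the search fragment tolerance was ±20 ppm);
one peak may satisfy several isobaric ions and is then flagged.

Localization is couplet counting, not probabilistic scoring. For each
candidate S/T/Y placement, the matched *site-determining* ions are those
whose m/z under this placement differs from their m/z under an
alternative (i.e. the fragment spans exactly one of the two sites). A
placement is pinned when, **against every alternative**, at least one
matched discriminating N-terminal-series ion and one C-terminal-series
ion exist — the flanking ion couplet. Exactly one pinned site ⇒
unambiguous; anything else ⇒ ambiguous (ties are never broken
arbitrarily); a composition without phosphates ⇒ unsupported. The
pairwise-against-every-alternative rule is deliberate: with three or
more candidate sites, an ion may discriminate one pair while being
shared by another, and pooling evidence across pairs can credit a wrong
placement.

## PSM pipeline

Delta masses within the open-search window (−50 to +600 Da) are
assigned via the matcher; others pass through unassigned. Class identity
pools Fe and Al adducts of a state — (chain length, metal count,
oxidations) — because the two adducts of one phosphorylation state are
the same biological species. The evidence filter requires ≥5 PSMs of a
class over all replicates. Condition comparison uses log₂ ratios of mean
per-replicate counts with a pseudo-count of 1 (classes can be absent on
one side entirely) and a Welch t-test by default: where only an
"unpaired two-sided t-test" is specified, the unequal-variance form is
the safer default for count data; the equal-variance form is a flag
away. Identical constant counts on both sides short-circuit to p = 1.

## Quantification

XIC areas use trapezoidal integration with linear interpolation at the
window edges, robust to irregular sampling. Percent contributions are
relative to the full-chromatogram area, then normalized to the most
abundant species (which reports 100%).

LFQ statistics follow the Perseus conventions: rows need ≥2 valid
values out of 4 replicates in at least one group; missing entries are
imputed **per sample** from 𝒩(μ − 1.8σ, (0.3σ)²) of that column's
observed log₂ intensities; the volcano uses a Student (equal-variance)
two-sample t-test with *no* multiple-testing adjustment — this
intentionally differs from the PSM-pipeline default (Welch), mirroring
the respective upstream tools. Significance: |log₂FC| > 1.5 and
−log₁₀p > 1.5. Permutation-based FDR is not implemented; reported
p-values are unadjusted by design.

## Targeting

Inclusion lists enumerate the cross product of phospho states (0–4) ×
admissible metal adducts (≤1 metal, requiring two chelating phosphates
per metal — "possible" adducts are interpreted through the same
chelation rule as the matcher) × Met oxidation (0–1) × charges 2–4.
Site permutations collapse to composition level because precursor m/z is
site-independent. A peptide containing Met and at least one S/T/Y yields
66 entries under the defaults.

## Motif screening

Two stretch definitions exist in the field's usage and both are
implemented: the default is 3–7 consecutive repeats of the *same* basic
residue (K, R or H); `class` mode accepts mixed K/R/H runs (≥4 by
default usage). Interrupted motifs are three basic residues with ≤2
interruptions between the first and last (KxKK, KKxK, …); windows fully
inside a reported stretch are suppressed and overlapping candidates are
deduplicated leftmost-longest, so the combined "stretches or motifs per
protein" ratio never double-counts. Whether a window with more than
three basic residues should count as both stretch and motif is
underdetermined; the suppression policy above is the documented choice.
Box-plot statistics use type-7 (linear-interpolation) quantiles, the
numpy default. Set comparison uses an unadjusted equal-variance
two-sample t-test on percent-basic-residue distributions.

## Structure metrics

Distances are Euclidean, in Å, from gemmi-parsed PDB or mmCIF models
with author residue numbering. "N1 of His118" maps to atom ND1 (the Nδ1
position that carries the 1-phosphohistidine intermediate). The
terminal atom of the phosphate chain is Pα/Pβ/Pγ for mono/pyro/tri
states (falling back to the phosphorus farthest from CB for
non-standard atom naming), and the minimum distance over the terminal
phosphate's oxygens (O atoms within 1.8 Å of the terminal P) is
reported alongside to bracket the value, since depositions do not name a
canonical atom pair. Tests run against synthetic stand-in models built
at reference geometries; they verify the measurement convention and
format round-trip (PDB vs mmCIF), not the deposited coordinates
themselves.

## Synthetic data

All generators hang off a single `SimConfig.seed`; identical seeds give
bit-identical outputs, and every generator emits ground truth.

* **PSM tables** (default 2,000 rows, 4 replicates): delta mass = class
  offset + 𝒩(0, 0.003 Da), class mixture dominated by unmodified/pyro
  states with Fe/Al-adducted chains at decreasing abundance — the
  regime of an ATP-treated pyrophosphoprotein digest.
* **Spectra**: theoretical b/y ions of the modified peptide
  (default VMLGETNPADSKPGTIR, the tryptic peptide around the
  modification site, candidate sites T6/S11/T15), thinned by a fragment
  efficiency (default 0.7), jittered by ppm error (default σ = 5 ppm),
  plus Poisson-count uniform noise peaks. Not modelled: isotope
  envelopes, chimeric spectra, intensity structure along the ladder.
* **LFQ matrices** (1,500 proteins, 80 enriched at log₂FC = 2,
  per-replicate σ = 0.5, 4+4 replicates): per-sample left-censoring
  drops values in the lowest ~31% intensity band with probability 0.8,
  giving ~25% missing-not-at-random missingness. Real LFQ data add
  peptide-level aggregation noise and batch structure not modelled here.
* **Proteomes**: i.i.d. residues at human-like frequencies with
  optionally planted stretches/motifs; chance background hits are
  flagged separately in the ground truth.
* **Chromatograms**: Gaussian peaks of specified area on a flat
  background, 0.25 s sampling.

Passing the synthetic-recovery tests shows the pipeline is correct under
its own model assumptions; it does not certify performance on real
spectra, where fragmentation efficiency, adduct dissociation and
intensity-dependent noise deviate from these idealizations.

## Problem sizes and expected statistical behaviour

The test suite and `scripts/acceptance.py` use: 200 random proteins
(>10⁴ peptides) for the digestion oracle; 500 (suite) / 300 (script)
planted-site spectra at 80% fragment efficiency and 3 ppm jitter; 10⁴
PSMs at σ = 0.003 Da for assignment accuracy; 20 seeded LFQ matrices for
enrichment recovery; 1,000 null proteins for t-test calibration; 1,000
random sequences for the motif oracle.

One recovery figure deserves a caveat. Under the LFQ generator's stated
conditions, the fold-change estimator has standard deviation
0.5·√(2/4) ≈ 0.354, so even an oracle analyst calls a cleanly observed
planted protein (true log₂FC = 2) above the 1.5 cutoff with probability
Φ(0.5/0.354) ≈ 0.92; proteins censored in part of the control group
additionally lose t-test significance through imputation variance
inflation, and planted proteins censored in both groups are
undetectable. The measured median sensitivity is therefore ≈0.87–0.88
(with median false-discovery proportion ≈0.01), which is the statistical
ceiling of these conditions rather than an implementation deficit; the
null calibration (type-I error ≈0.05) and the near-zero FDP are the
checks that the statistics themselves are sound.

## Known limitations

* No FDR machinery, spectral recalibration, or probabilistic
  localization scores (Ascore/ptmRS) — out of scope by design.
* Average (non-monoisotopic) masses and isotope distributions are not
  computed.
* Metal-adduct retention on fragments is an assumption, not a measured
  dissociation model.
* The structure module measures distances only; it performs no map
  handling, refinement or symmetry expansion.
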