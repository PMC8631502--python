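# Methods

This note documents the models behind `fishglycomics`, the assumptions they
make, the numerical conventions, and what the synthetic-data generator does
and does not emulate.

## Mass model

A glycan is represented at two levels. A **composition** counts residues of
the classes distinguishable by mass alone — Hex, HexNAc, dHex and the
sialic-acid family (NeuAc, NeuGc, KDN) — plus *O*-acetyl groups. A
**topology** is a rooted tree of named residues (Gal/Man/Glc, GlcNAc/GalNAc,
Fuc) with an anomeric configuration per edge. Hexose identity is carried on
topologies but deliberately erased in compositions: MS1 cannot distinguish
hexoses, and identity is only ever inferred through exoglycosidase
specificity or MSn fragmentation. Linkage positions are optional and never
required for matching; motif matching uses anomericity only.

Neutral masses are sums of residue (dehydro-monosaccharide) masses plus an
end-group constant: +18.01056 Da (H₂O) for the free-reducing native glycan,
+46.04186 Da (C₂H₆O) after permethylation, which also adds 14.01565 Da per
free hydroxyl/amide site (3 for Hex and HexNAc, 2 for dHex, 5 for NeuAc, 6
for NeuGc and KDN). *O*-acetylation adds 42.01057 Da per group and exists
only on native glycans — the permethylation reaction removes base-labile
modifications, and the code enforces this incompatibility.

Isotope envelopes are computed by per-element convolution of isotope
polynomials (¹³C 1.07%, ²H 0.0115%, ¹⁵N 0.364%, ¹⁷O 0.038%, ¹⁸O 0.205%)
with truncation at A+6. The isotopologue step is taken as the ¹³C−¹²C
difference, 1.00336 Da; at glycan masses the error from lumping the other
heavy isotopes into this step is well below display precision. Observed
profile peaks correspond to the envelope maximum (A+1 near 3 kDa, A+2 from
about 4 kDa), so every m/z routine takes an explicit isotopologue index k
and a most-abundant-k convenience exists. m/z values are displayed at two
decimals with half-up rounding, matching instrument software.

Positive mode pairs with permethylation and per-charge sodiation
([M+zNa]ᶻ⁺, z = 1..4); negative mode pairs with native glycans and
per-charge proton loss ([M−zH]ᶻ⁻ — the standard assumption for
underivatized glycans infused in ammonium-acetate systems).

## Fragment model

Only B-type, singly charged, sodiated fragments are predicted; they carry
every topology argument the package makes (branched vs linear trihexose
caps, the di-SA B-ion at m/z 759.35, the catfish epitope chain
1051.5 → 676.3). A glycosidic cleavage leaves the departing (non-reducing)
piece fully methylated and the retained piece with one unmethylated
hydroxyl "scar" worth −CH₂; scars are tracked per node as a multiset, so a
branch point that loses two substituents correctly carries two scars.
Sequential MSn stages are modelled as repeated cleavages with a
configurable depth. Y-type ions of the multiply charged molecular ion and
cross-ring (A/X) cleavages are out of scope. The tree-walk prediction and
the composition-level B-fragment formula are verified against each other in
the tests (dual route).

## Peak processing and assignment

Isotope clusters are collapsed by walking outward from intensity-ordered
seed peaks at 1.00336/z spacing for z = 1..4 (±0.05 m/z default). The
winning charge hypothesis explains the most peaks (a subharmonic z′ of the
true z only reaches every (z/z′)-th member), then minimizes spacing
residuals, ties to lower z. Edge members far weaker than the envelope
maximum (leading member < 25% of its successor or any member < 5% of the
maximum) are excluded from the m/z estimate — an absorbed spurious peak in
front of the envelope would otherwise shift the whole cluster by one
neutron. The cluster's monoisotopic m/z is the unweighted mean of all
members shifted back by their offsets, which shrinks jitter by √n.

Clusters of the same neutral mass across charge states are pooled
("peaks for all charge states were summed"), combining their monoisotopic
estimates with precision weights (n_members/z²), and each pool is assigned
once. Candidate compositions come from an exhaustive search within
configurable bounds (defaults: NeuAc 0–6, Hex 3–14, HexNAc 2–8, dHex 0–3,
NeuGc 0–2, KDN 0–2); NeuGc and KDN are *searched* even though these sera
lack them, so their absence is a result, not an assumption.

Ranking had to confront the exact degeneracies of glycan composition space:
NeuGc₁dHex₁ and KDN₁HexNAc₁ are elementally identical to NeuAc₁Hex₁, and
the substitution 3·NeuAc ↔ 2·dHex + 3·HexNAc (36.4 mDa) or
3·NeuAc ↔ 2·dHex + 6·Hex − 2·HexNAc (one neutron minus 6.7 mDa) produces
near-twins. The order is:

1. envelope plausibility — an observed profile peak is the envelope top, so
   candidates matched far from their own most-abundant isotopologue are
   demoted; in monoisotopic matching, a "monoisotopic member missing"
   (k = 1 start) hypothesis is only credible if the candidate's own
   envelope predicts a weak monoisotopic peak (p₀/p₁ ≤ 0.3);
2. fewer rare sialic acids (NeuGc + KDN) — the common-residue explanation
   of an exact collision is preferred outright, and rare candidates remain
   visible in the collision audit;
3. mass error, binned at 1 ppm above the best hit so that genuinely
   distinct masses rank by nearness while exact degeneracies fall through
   to parsimony (fewer residues), then smaller k.

Every multi-candidate match is reported in the audit log; nothing is
silently chosen.

The detection threshold retains compositions whose summed response is at
least 3% of the most intense single MS1 peak (the base peak). Referencing
the base peak rather than the largest per-composition total matters: a
summed response is several-fold its base peak, and a total-referenced
cutoff would silently drop the sub-percent glycans (0.1–0.4% of the pool)
that the protocol demonstrably quantified.

Quantification against the Dp4 (permethylated maltotetraose) internal
standard uses `amount = I/I_std × standard_amount / spike_fraction` with a
5% default spike. The theoretical [M+Na]⁺ of permethylated maltotetraose
is 885.43; the source protocol logged the standard at m/z 899.48 (one CH₂
higher, unexplained), so the expected standard position is a configuration
value defaulting to theory.

## Digestion model

α-Galactosidase removes terminal α-Gal; β-galactosidase removes terminal
β-Gal unless the parent residue carries a blocking branch — a sialic acid
(the catfish NeuAc-branched GalβGalβ cap resists both enzymes) or an α-Gal
(the sturgeon Galα(Galβ)Galβ cap must be treated with α before β, which is
why digestion order is α-first). Exhaustive digestion repeats passes until
no residue is eligible, so newly exposed termini become substrates.
Digestion is terminal-only and never adds residues; each removed hexose
lowers the permethylated mass by exactly 204.09977 Da. Partial digestion
("steric interference" on highly complex structures) is modelled in
simulation as a per-site success probability, default 1.0. The
composition-level interpreter reports before/after residue differences and
flags losses outside the enzyme's specificity as inconsistent rather than
accepting them.

## Synthetic data: what it emulates and what it does not

The generator emits centroided MS1 peak lists: per glycan, isotope clusters
to depth A+4 at the preset's charge-state mixing weights (only charge
states whose cluster lies inside the 600–2000 scan window carry signal,
renormalized per glycan so summed intensity stays proportional to true
abundance), plus the Dp4 standard in permethylated mode, m/z jitter
(σ = 0.01), multiplicative intensity noise (CV = 10%) and spurious peaks
(5 per 100 true peaks). In native mode each sialylated glycan's abundance
is spread over the species' *O*-acetyl ladder (salmon to 3 groups, char to
6, Atlantic sturgeon to 1, catfish to 2, capped at 3 per sialic acid — the
per-sialic cap is configurable because the 6-OAc char species' 3+3
distribution is an assumption).

The five presets pin every species-level quantity the study established:
the dominant biantennary disialylated glycan; di-SA prevalence 2%
(salmon) / 5% (char); the triantennary trisialylated glycan abundant in
salmon and absent from char; tetrasialylated di-SA glycans at 0.38% and
0.12%; core fucosylation on >40% (actual preset: 45%) vs 2% of the
sturgeon pools; the catfish profile centred on NeuAc₂Hex₇HexNAc₄ with the
NeuAc-branched GalβGalβ epitope and no salmonid NeuAc₃Hex₅HexNAc₄.
Abundances the study did not print are filled with plausible values and
flagged `abundance_from_study = false` in the ground truth.

Not emulated: profile-mode (non-centroided) signals, chromatographic or
mobility dimensions, in-source fragmentation artifacts, glycopeptides,
detector saturation, and calibration drift (jitter is i.i.d., not
systematic). A green round-trip test therefore establishes that the
pipeline inverts its own stated instrument model — not that it would
survive raw instrument data unchanged.

## Statistical behaviour and test design

With the stated noise, a single simulated sample carries irreducible
share-level noise (≈0.5–1 percentage point 1σ on a 60% glycan after
renormalization). Feature-recovery checks therefore average three
simulated replicates, mirroring the three-biological-replicate design of
the underlying protocol; replicate-averaged features recover preset truth
within ±1.5 percentage points in ≈99.5% of trials, with rare (<5%)
noise-tail excursions that the acceptance test bounds explicitly. The
fuzzed composition round trip (isotope clusters at two random charge
states, Gaussian jitter truncated at ±0.01 m/z) achieves ≥99% top-1
recovery over the NeuAc-family composition space while searching the full
bounds including NeuGc/KDN; recovery over compositions *containing*
NeuGc/KDN is impossible in principle because of the exact degeneracies
above, which is precisely why the assignment prefers common residues and
audits collisions.

## Known limitations

* Antenna fucosylation is indistinguishable from core fucosylation in
  MS1-only data; all dHex is reported as "core fucose" with this caveat.
* The di-SA count from composition (`NeuAc − antennae`) is a heuristic;
  topology-level counts override it when a topology is known.
* The isotopologue convention of instrument peak-picking is not perfectly
  consistent in practice (the same molecule can be logged at A+1 for one
  charge state and A+2 for another); the engine exposes both explicit-k
  and most-abundant-k interfaces for this reason.
* Only galactosidases are modelled; sialidases and other exoglycosidases
  would need new `DigestRule` entries (the rule machinery supports them).
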