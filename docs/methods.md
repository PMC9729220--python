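# Methods

## Model and procedure

The package models the readout chain of a restriction-enzyme-mediated
translesion-synthesis assay as five composable stages.

**1. Construct design.** The control insert STD
(`AATTCTCCTGCAGGCTAGCACTGA`) carries a PstI site at positions 8–13. The four
lesion constructs X13–X16 substitute the L-nucleoside of base X at site
offsets 2–5 (insert positions 9–12); the name→offset map `{13:2, 14:3, 15:4,
16:5}` is fixed by the published oligonucleotide set, not derived. Each
construct detects the single incorporated base whose complement restores
`CTGCAG` in the progeny: X13 detects dA, X14 dC, X15 dG, X16 T. Outcome
labels report the progeny base at the lesion position (e.g. G13 detection is
"l-dG → T"); when the progeny base equals the lesion base the outcome is the
correct Watson–Crick read-through. `decode_table` verifies by exhaustive
enumeration that each construct has exactly one restoring incorporation and
that the four detections are a permutation of {A,C,G,T}; any violation is a
hard `DesignError`.

**2. Annealing and duplex bookkeeping.** Annealing is ungapped sliding of
one strand against the other, scored by Watson–Crick match count, requiring
a unique maximum of ≥ 12 matches (assay duplexes share a 20-bp core; gapped
annealing is out of scope). Chirality never affects complementarity — an L
base pairs by its base letter and the flag only marks the lesion — so the
engineered C:C mismatch and the lesion's own mismatch (when the lesion base
differs from the base it replaced) are both represented in the pairing map.
Coordinates are 1-based, 5'→3' per strand.

**3. Digestion.** Site recognition is strictly double-stranded: all six
positions must be paired and mismatch-free. One mismatch abolishes the site
entirely (no partial-activity model); this all-or-none rule is what makes
the complement-strand progeny (`CTGCAC`) and the original mismatched
hetero-duplex uncuttable, i.e. it is the strand-discrimination mechanism
itself. Digestion is simultaneous and complete; each strand is cut at its
own offset, and fragments are reported as single strands, as resolved on a
denaturing gel. An L sugar inside a site does not block cutting by default
(the assay digests all-D PCR products); a `chirality_blocks` flag exposes
the alternative.

**4. Replication simulator.** Per template: bypass with probability β;
conditional on bypass, incorporation drawn from π (optionally an indel with
probability `indel_prob`, default 0, matching the observed absence of
insertions/deletions — the channel exists so the 24-mer length check is
exercisable). The control behaves as β = 1 with the correct base; blocked
templates leave no full-length product; the complement strand replicates
once per template regardless. `expected_pool` replaces all draws by their
means, giving the deterministic noise-free limit in which estimator recovery
is exact to floating precision — this pins down the estimator algebra
independently of Monte-Carlo error. PCR is modeled as a linear unbiased
readout of template composition: the assay only ever uses ratios against an
identically amplified control, so any common gain cancels.

**5. Gel synthesis and quantification.** Band mean intensity is
(moles × fragment length), i.e. mass-proportional SYBR staining, with i.i.d.
multiplicative log-normal noise per band (σ is the SD of log intensity;
default 0.05 — the wet assay reports single-gel measurements with no error
model, so a simple explicit one is used and exposed in config). The
EcoRI+HindIII protocol digests the input recombinant pool (the construction
check), so the 24-mer band tracks loaded material and is independent of
bypass; digesting post-replication pools instead would make the loading
denominator depend on (1+β) and bias recovery. The PstI+HindIII protocol
digests the progeny pool. Bands below a detection floor (default 1% of the
control's diagnostic band) are reported absent, mirroring a binary
band-present/absent reading, and absent bands enter the estimator as
e_k = 0 rather than as censored values. A self-ligation background band
(configurable length, default 16 nt; the vector's polylinker is not
published, so the length is a parameter rather than derived) can be added
to PstI+HindIII lanes at a stated fraction of the control signal; it is
appended after the main noise draws so its presence never perturbs any
other band, and it never collides with the 20/24-mer bins.

The estimators are as in the README. Loading normalization by the 24-mer
band is on by default; because the underlying protocol wording is ambiguous
about it, a flag selects the unnormalized variant, and the two coincide
exactly under equal loading. Percentages are rounded only for display; when
RBE = 0 mutation frequencies are flagged undefined rather than NaN.

## Amplicon context

The PCR-product sequence outside the insert is not part of the published
materials. The package uses synthetic 23-nt flanks
(`TTAGCTCACTCATTAGGCACCCG` / `AGCTTGCGTAATAGCGAAGAGGC`) that regenerate the
EcoRI and HindIII junctions exactly as ligation into an EcoRI/HindIII-cut
vector would, begin and end with the assay's PCR primer sequences, and
contain no spurious recognition sites (asserted by the brute-force digest
oracle in the tests). With these flanks the 70-bp amplicon reproduces the
diagnostic band logic: 24-mer insert strands under EcoRI+HindIII, and the
20-mer `AGCTTCAGTGCTAGCCTGCA` under PstI+HindIII iff the site is restored.

## Parameters that matter

| parameter | meaning | default | why |
|---|---|---|---|
| β | bypass probability per template | scenario | the quantity the assay estimates |
| π | incorporation distribution opposite the lesion | scenario | determines the mutation spectrum |
| `n_templates` | templates per construct | 100 000 | binomial error ≪ gel noise |
| σ | SD of log band intensity | 0.05 | few-percent densitometry repeatability |
| `replicates` / `seeds` | gel re-measurements | scenario | replicates share one progeny pool and differ only by noise |
| `pool_seed` | replication draw seed | derived from first replicate seed | separates biology from measurement noise |
| `detection_floor` | absent-band threshold | 0.01 of control band | binary band readout |
| `background_16mer` | self-ligation band level | 0 | cosmetic; never interferes |

All randomness flows through explicit integer seeds (numpy `default_rng`);
wall-clock seeding is unsupported. Replicate gels use seeds `2s` and `2s+1`
for the two protocols so the streams are independent but reproducible.

## What the synthetic data does and does not emulate

The generator reproduces the *statistical structure the quantification
assumes*: per-construct 20-mer/24-mer intensities proportional to the
fraction of templates replicated past the lesion with a given incorporated
base, under multiplicative noise. It does not emulate PCR amplification
bias or saturation, ligation/transformation efficiency differences between
constructs, gel smearing or lane warping, partial digestion, or polymerase
kinetics. Consequently, passing recovery tests demonstrates that the
estimator chain is correct and well-conditioned under the assay's own
assumptions — not that those assumptions hold on any particular wet
dataset. In cells, the measured β may also fold in transformation
efficiency; the simulator deliberately exposes only a single β and does not
attempt to separate the two.

## Numerical and design choices

- **Recovery study size.** Acceptance-style recovery uses 10 replicate
  gels at n = 10⁵ templates and σ = 0.05. Under these conditions the
  replicate-mean RBE has a standard error of about 3% of its value (four
  independent log-normal factors per e_k ⇒ per-replicate log-SD ≈ 0.10),
  so recovered means sit within ~±3 percentage points of truth for large
  RBEs and much closer for small ones; estimates are unbiased up to a
  +0.5%-relative log-normal mean offset, which is negligible at σ = 0.05.
- **Bootstrap.** Percentile bootstrap over replicate gels (default 1000
  resamples). With 10 replicates nominal 95% intervals cover the true β
  slightly below nominal (≈92–94%), as expected for percentile intervals at
  small n; the test suite checks ≥ 90% over 50 seeded scenarios.
- **Ties and degenerate inputs.** Annealing raises on ambiguous best
  alignments rather than guessing; `quantify` refuses band tables missing
  any of the five samples under either protocol; a missing construct 24-mer
  is a construction failure (`DataError`), a missing/zero control band a
  `ControlError`; bootstrap refuses < 2 replicates.
- **Outcome label for the "two times higher" phrasing.** The printed
  65%/35% Vent l-dG split is used as-is (its ratio is 1.86, not 2).

## Known limitations

- Only ungapped, unique-best annealing; no thermodynamics, no IUPAC codes.
- Enzymes are complete-digest, no star activity or methylation sensitivity;
  non-palindromic sites are representable via explicit bottom-strand cut
  offsets but only the three palindromic built-ins are exercised.
- The 16-mer background length is a parameter, not derived from a vector
  sequence.
- Replicates model measurement noise only; biological replication noise can
  be emulated by varying `pool_seed` across runs but is not a first-class
  replicate axis.
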