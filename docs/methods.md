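# Methods

This note documents the models, criteria, numerical conventions and design
choices behind `dyncontact`, and what its validation does and does not
demonstrate.

## Contact model

Contacts are binary per frame and keyed by a canonical (lexicographically
ordered) residue pair; ligand residues are keyed `LIG:<resname>`.  All
boundary comparisons are inclusive (≤ / ≥) so ties resolve
deterministically.  Default criteria (all exposed in `ContactCriteria`):

| class | criterion | default |
|---|---|---|
| hydrogen bond | donor–acceptor heavy-atom distance; donor–H–acceptor angle when hydrogens exist | ≤ 3.5 Å; ≥ 110° |
| water bridge | one water hydrogen-bonded (same criterion) to polar atoms of two different protein/ligand residues in the same frame | single water only |
| salt bridge | any cationic-group N to anionic-group O | ≤ 4.0 Å |
| π-stack | ring-centroid distance; inter-normal angle | ≤ 7.0 Å; ≤ 30° or ≥ 150° |
| van der Waals | heavy-atom distance ≤ r_i + r_j + pad (Bondi radii) | pad 0.5 Å |

These values follow the documented conventions of the GetContacts family
of contact-analysis tools.  Directionality is enforced for water bridges
(water donates only to acceptors; a protein donor donates through its own
hydrogen).  Hydrogen-free topologies (crystal structures) degrade to
distance-only hydrogen-bond detection.  Intra-residue pairs are never
contacts; van der Waals additionally excludes sequence-adjacent
backbone-only pairs and any residue pair already hydrogen-bonded or
salt-bridged in the same frame (avoiding double counting in fingerprints,
while each class remains a separate fingerprint row).

Chemical annotations (donors/acceptors, charged groups, aromatic rings)
come from atom-name templates for the 20 standard amino acids, a water
template, user-registered ligand templates, and a dynamic naming
convention for synthetic residues.  Unknown ligands fall back to
vdW-only annotation with a warning.

Two candidate-generation paths exist — vectorised all-candidate-pairs and
k-d-tree pruning (`scipy.spatial.cKDTree`, prune radius slightly above the
criterion threshold so the subsequent exact test decides) — and are
verified to agree exactly with an independently coded O(n²) reference on
random configurations.  The vectorised path is used by default up to a few
hundred atoms and processes frames in chunks to bound memory.

## Frequencies, Δ_freq and the filter

Frequency is the per-frame indicator average over the analysed window
(multiple events of one key in a frame count once), computed after
discarding the equilibration-biased start of each replica — by default the
first 10 % of frames, generalising the convention of analysing a 1 µs
trajectory from 100 ns; window slicing is inclusive of both endpoints.
The fingerprint cutoff retains a key if its frequency reaches 0.5
(residue–residue) or 0.3 (ligand–protein) in **at least one** replica of
either condition; cutoffs are applied before testing.

Δ_freq = mean(Freq_A) − mean(Freq_B) over per-replica frequencies, with
condition A the modulator-bound ensemble by convention.  Significance is a
two-sided two-sample Student's t-test (pooled variance; Welch by flag) on
the per-replica frequencies — replicas, not frames, are the sampling
units.  Degenerate cases: both samples constant and equal → p = 1;
constant but different → p = 0 with a warning.  The network keeps records
with p < 0.05 **and** |Δ_freq| > 0.4, both strict.  No multiple-testing
correction is applied — deliberately, with the large effect-size gate as
the practical false-positive control; the validation suite measures the
resulting error rates (below).

Switches are residue triples (X, Z, Y) where passing hydrogen-bond records
X–Z and Y–Z share Z with opposite-signed Δ_freq, ranked by the smaller
|Δ_freq| of the pair; the A-enriched partner is listed first.  Per-class
testing (not class-pooled) is used throughout; ligand fingerprint tables
pool classes per residue at the event level (union of contact frames).

## Structural and energetic metrics

Superposition is the orthogonal-Procrustes/Kabsch fit
(`scipy.spatial.transform.Rotation.align_vectors`).  RMSF is per residue:
the average over the residue's heavy atoms of each atom's
√⟨|x − ⟨x⟩|²⟩ after optional superposition on a stable selection; for
isotropic per-axis Gaussian noise σ this equals σ√3, which the tests use
as a closed-form oracle.  Ligand RMSD superposes on the receptor only and
never re-fits the ligand, so binding-site exit produces large values.

The binding-energy surrogate is a pairwise inter-group nonbonded energy:
Coulomb 332.0636·q_iq_j/r plus Lennard-Jones
ε_ij[(r_min,ij/r)¹² − 2(r_min,ij/r)⁶] with Lorentz–Berthelot-style
combination (r_min,ij = r_min,i/2 + r_min,j/2, ε_ij = √(ε_iε_j)), each
term multiplied by the CHARMM switching polynomial on 10–12 Å with a 12 Å
cutoff.  It is **not** a binding free energy: no solvation, entropy or
long-range electrostatics.  Only relative quantities computed from it —
condition means, percent differences
100·(|E_ref| − |E_alt|)/|E_alt|, and truncation-variant ΔΔE — are
meaningful, and only those are validated.  When no parameter table is
supplied, element-level defaults (CHARMM-like magnitudes) are filled in.

Ballesteros–Weinstein labels are h.(50 + r − anchor_h) inside
user-declared helix spans; anchors are receptor-specific configuration
(two-to-four-column text: helix, anchor, optional span), since conserved
x.50 positions cannot be derived from a topology alone.

## Synthetic ensembles: what they emulate

`syntraj` emulates the study design — two conditions × 5 replicas ×
~10³ frames — not molecular physics.  Residue bodies sit on a 30 Å grid;
each scheduled contact owns dedicated probe atoms and a private rendezvous
site, placed in ideal mid-threshold geometry (donor–acceptor 2.9 Å
collinear; salt bridge 3.5 Å; eclipsed rings 4.5 Å apart; carbons 3.5 Å;
water symmetric at 2.8 Å) in frames where an independent Bernoulli draw
with the condition's probability succeeds, and parked ≥ 10 Å away
otherwise.  Isotropic Gaussian jitter (default σ = 0.05 Å, configurable
per residue) is added to every atom; margins are ≥ 0.3 Å so jitter up to
σ ≈ 0.1 Å cannot flip a contact state.  Replica streams derive from
`SeedSequence([seed, crc32(condition|replica)])`, making replicas
independent yet bit-reproducible across processes.  Timestamps are
dt·frame_index ns from 0.

Consequently, passing tests demonstrate that detection, fingerprinting,
the Δ_freq statistic, its error rates and the switch logic behave
correctly under the stated sampling model.  They do not demonstrate
robustness to correlated frames (real MD frames are autocorrelated, so the
per-replica design matters there even more), to force-field artefacts, to
ambiguous border geometries, or to imperfect chemical annotation of
nonstandard residues.

## Validation design and measured behaviour

The validation suite recomputes, at run time:

- frequency recovery within the ±0.05 binomial band at 10³ frames for
  every interaction class;
- filter power for programmed |Δp| = 0.5 contacts and the full-filter
  false-positive rate on programmed nulls, over 100 seeded 5+5 ensembles;
- t-test-only type-I calibration over 200 null contacts (expected ≈ 5 %,
  accepted band 2–9 %);
- exact grid/brute-force agreement on random configurations;
- RMSF σ√3 recovery within 5 % at 2000 frames;
- switch detection on the anti-correlated hydrogen-bond motif;
- byte-identical pipeline reruns.

Problem sizes (10³ frames, 5 replicas, ≤ ~40 residues, 100-run
resampling) match the study design where one is stated and otherwise were
chosen once as the smallest sizes at which the binomial and t-distribution
asymptotics the checks rely on are comfortably valid.

## Known limitations

- PDB/DCD only (via biotite/MDAnalysis); no PSF/PRMTOP/XTC.
- Single-water bridges only; no cation-π; no two-water chains.
- The energy surrogate's absolute values are physically meaningless.
- The t-test treats replica frequencies as i.i.d. normal; with 5 replicas
  the calibration band, not exact nominal level, is the realistic claim.
- Fingerprint cutoffs, thresholds and the 0.4 effect gate are conventions
  of the analysed workflow, exposed as configuration rather than inferred
  from data.
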