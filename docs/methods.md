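# Methods

## Conditioning model

`pharmdiff` treats a pretrained diffusion denoiser as a black box exposing
one reverse step: given the current state (positions R^t, types, bonds) it
returns Gaussian position means μ_θ, categorical atom-type logits H_θ, and
bond logits, with a step variance Σ_t taken from the schedule (Σ_t = β_t by
default). Conditioning modifies the transition only:

1. **Guidance shift.** The sampling mean becomes μ_θ − λ·Σ_t·∇L(R^t). The
   clash loss is L(R) = Σ_i max(0, d_clash − S(r_i))² over the smoothed
   surface field S(r) = −σ·log Σ_j exp(−‖r − a_j‖/σ), a soft minimum over
   protein heavy-atom distances (always a lower bound on the true minimum
   distance; exact as σ → 0). The gradient is analytic — softmax-weighted
   unit vectors scaled by the hinge — and is evaluated at the current sample
   R^t (evaluation at μ_θ is available via `GuidanceConfig.grad_at`).
2. **Sampling.** R^{t−1} = mean + √Σ_t · ε, with no noise added at the final
   step so the chain terminates on its mean.
3. **Anchoring.** Masked slot i is blended toward its bound pharmacophore
   point: r_i ← (1 − γ_t)·r_i + γ_t·p̂_i. Slot k is permanently bound to
   point k; there is no reassignment during sampling.
4. **Type clamping.** User-fixed elements overwrite masked slots; every other
   slot takes the modal category of H_θ. Bond states are taken from the
   denoiser unchanged.

### Anchoring schedule

γ_t = min(1, (1 − t/T)² / (1 − f)), clipped to exactly 1 for the final
⌈f·T⌉ reverse steps with f = 0.1. This realizes "move slightly toward the
constraints early, anchor firmly late": γ is monotone non-increasing in t,
near zero at t = T, and the hard-anchor window makes the terminal masked
positions *bit-exactly* equal to the points. Both the functional form and f
are replaceable (`ScheduleSpec.gamma`); the constructor enforces monotonicity
and the hard window.

### Reference-point treatment and initialization (ablation modes)

- `around_points` (default): initial positions are Gaussian draws around the
  bound point (masked slots) or the point centroid (free slots), spread
  1.0 Å; reference points are used at their original coordinates, un-noised.
- `pure_random`: initialization around the pocket center instead.
- `noised_reference`: initialization as in the default, but the anchoring
  targets are re-noised each step with the forward-process scaling
  √ᾱ_t·p̂ + √(1 − ᾱ_t)·ε.

The three modes correspond to the standard initialization/reference
ablations for this family of conditioning methods.

### Satisfaction and retry

A pose satisfies a point when some atom within τ (default 1.0 Å) matches the
point's family, where family membership is decided by the same shipped SMARTS
sets used for extraction (a strict mode restricts the match to the bound slot
atom). Each requested ligand is granted up to `max_attempts` = 3 full
trajectories; the first satisfying pose is accepted and every rejection is
recorded in the generation report. Note that with hard anchoring a
*geometric* constraint is always met by its own anchored atom; rejection in
practice comes from the family check (e.g. a slot whose element cannot carry
the feature).

### Randomness

All draws flow from one seed through `SeedSequence(entropy=seed,
spawn_key=(ligand, attempt))`, so each (ligand, attempt) trajectory is an
independent, individually reproducible stream. The trajectory driver takes
every Gaussian draw from an injectable `eps_fn`, which is how the test suite
verifies exact E(3) equivariance (rotating the inputs and the noise rotates
the outputs to < 1e−8 Å).

## Toy system

The fixture generator emulates the minimum structure the conditioning loop
needs: a convex pocket (200 points on a radius-8 Å spherical shell with a
polar opening; mostly carbon with O/N sprinkled in), and a tree-bonded
template ligand (12 heavy atoms, vocabulary {C, N, O}, single bonds, bond
length 1.5 Å) centered inside it with one hydroxyl-like O leaf
(donor + acceptor) and one amine-like N leaf. Template atoms stay within
radius − 4 Å of the center because the soft-min surface runs ~1–2 Å below
the true minimum distance for a dense shell; the generator verifies
S > d_clash for every template atom and regenerates on failure
(`GenerationError` after 100 rejections). The pocket uses σ = 0.5 Å and
d_clash = 2.0 Å; read-in proteins default to σ = 1.0 Å, and both constants
are configurable per context.

The toy denoiser returns the exact DDPM posterior mean of r^{t−1} given r^t
and r₀ = template, computed about the template centroid so the closed form
is equivariant under rotations *and* translations (the centered-coordinate
convention of molecular diffusion models). Schedule: T = 50, β linear
1e−4 → 0.1 — small enough for seconds-scale tests, long enough for
non-trivial trajectories. Type and bond logits are one-hot in the template.

**What passing toy tests do and do not show.** The toy chain collapses onto
its template: at t = 1 the posterior mean equals r₀ exactly, so terminal
poses are nearly deterministic, generated sets have zero diversity, and the
ablation modes are distinguished by their trajectories rather than their end
points. The tests therefore demonstrate the *mechanics* — exact anchoring,
correct gradients, schedule handling, equivariance, retry accounting — not
generative quality on real chemistry, which depends entirely on the plugged
-in denoiser. The synthetic pocket also lacks real protein features:
residue-level chemistry, backbone topology, and crystallographic waters.

## Metric suite

- **H-bond detection** is a geometric heavy-atom scan: ligand hydrogens are
  added with inferred coordinates if absent; a ligand donor D forms a bond
  to a protein acceptor O when dist(D, A) ≤ 3.5 Å and some D–H makes a
  D–H···A angle ≥ 120°; the ligand-acceptor direction pairs ligand acceptors
  with protein N donors on the distance criterion alone, since heavy-atom
  protein contexts carry no protons for an angle test. Both constants live
  in `MetricConfig`.
- **Interaction similarity** counts reference (protein residue, ligand role)
  bond keys recovered by the generated pose, divided by the reference's key
  count — pose-independent, capped at 1 by construction. Undefined (raises)
  when the reference forms no bonds.
- **SC similarity** is the unweighted mean (weights configurable) of a
  volumetric shape-overlap similarity and a feature-map "color" similarity
  over donor/acceptor/aromatic/hydrophobe/ionizable families, both computed
  in place with no realignment. If neither conformer has any pharmacophoric
  feature the color term is vacuously 1; if exactly one has none, it is 0.
- **SA** implements the Ertl fragment-contribution score (historical
  fragment-frequency table, plus size/stereo/spiro/bridgehead/macrocycle
  penalties and the symmetry correction), reported on a normalized scale
  (10 − raw)/9 so that high = easier to synthesize.
- **QED, filters, fingerprints** use the standard published
  parameterizations as shipped with the cheminformatics toolkit
  (NIH/PAINS/Brenk catalogs; Morgan radius 2, 2048 bits for diversity).
- **Success rate** per pocket: validity flag (external adapter, or all-true
  offline) AND NIH pass AND QED ≥ 0.19 AND SA ≥ 0.33 (defaults; thresholds
  are arguments), with pockets yielding zero passers tallied separately.
- **Top-k selection** ranks by SC descending with stable ties; downstream
  metrics report the best value within the subset.
- **Docking normalization** divides a score by √N to deflate size bias; the
  docking and pose-validity tools themselves are external adapters
  (subprocess + file exchange) with labeled offline stubs.

## Numerical choices and degenerate inputs

- Coordinates are Cartesian Å throughout; no unit conversion anywhere.
- Soft-min gradients guard the r = a_j singularity with a 1e−12 distance
  floor; non-clashing atoms get exactly zero gradient rows.
- Fragment selection breaks heavy-atom-count ties toward the fragment
  containing the smallest original atom index (order-stable).
- An empty constraint spec with `around_points` initialization falls back to
  `pure_random` with a warning; an empty pocket context is an error.
- Satisfaction of a pose whose graph fails sanitization treats the molecule
  as featureless (all points unsatisfied) rather than erroring, so malformed
  intermediate poses are rejected, not fatal.
- Atom types and bonds are taken as the modal category of the denoiser's
  logits each step rather than sampled; for the toy denoiser's one-hot
  logits this is exact, and it keeps trajectories reproducible bit-for-bit
  under shared seeds. A stochastic type sampler would be a denoiser-side
  extension.

## Problem sizes

Default study sizes used by the test suite and the acceptance script: toy
complexes with 12 heavy atoms and 200 pocket points; 50-ligand generation
runs; 60–100 paired seeds for the guidance comparison; 100 randomized cases
per oracle-equivalence check; 200 seeded runs for unconditional recovery.

## Known limitations

- Donor/acceptor are the only built-in pharmacophore families (the enum and
  SMARTS data file are extensible); lipophilic/aromatic/charge features and
  hotspot-derived pharmacophores are out of scope.
- No protonation-state or tautomer handling; hydrogens are kept as given and
  added only where a metric needs them.
- The protein-side H-bond criterion is distance-only (no protons available).
- mmCIF input is not supported; PDB reading keeps altloc blank/'A' and the
  first model only.
- The `moldiff` checkpoint adapter is a documented stub; wiring a trained
  model is the user's responsibility.
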