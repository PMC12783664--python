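# Methods

This note records the models, parameter choices and numerical decisions
behind `sonoglyph`, and what the packaged simulations do and do not show.

## Sonification model

The encoder is an additive oscillator bank. For an `n×n` image (`n = 64`)
one image axis indexes `n` oscillators at geometrically spaced frequencies

f(i) = f_min · (f_max/f_min)^(i/(n−1)),  i = 0 … n−1,

so log-frequency is affine in the step index and both endpoints (500 and
5000 Hz by default) are attained exactly at the first and last steps.
Geometric interpolation is the simplest law that is logarithmic and hits
both stated endpoints; whether a deployed device attains the endpoints at
row centres or edges is a configuration point (`f_min`, `f_max`,
`n_steps`), not a structural choice.

The other axis is scanned as time in `n` steps of `column_duration`
seconds each. `column_duration` defaults to exactly `1.05/64 s`
(16.40625 ms) so the sonification lasts exactly 1.05 s; step boundaries
use cumulative rounding, `boundary(c) = round(c · column_duration · sr)`,
which makes the total sample count exact (46 305 samples at 44.1 kHz) at
the cost of one-sample variation between steps. Each active pixel
contributes `b · w(t) · sin(2π f t)` where `t` is measured from
sonification onset (phase-continuous oscillators, phase 0 at onset) and
`w` is a unit gate over the pixel's time step with raised-cosine edge
ramps (default 1 ms; configurable to 0 for the analytically exact
rectangular gate). Ramps are confined inside each step, so synthesis
remains strictly linear in brightness with per-(row, step) atoms of
disjoint cross-step support — the property the decoder relies on. The
summed sonification is peak-normalised to 0.9; all-silent input stays
silent.

The onset cue is a deterministic raised-cosine-windowed 2500 Hz burst of
`round(0.0033 · sr)` samples (146 at 44.1 kHz, i.e. 3.31 ms) at peak 0.9.
Only its duration and position are constrained by the protocol it
emulates; the carrier and window are this package's choice, made for
reproducibility and a distinct broadband-ish timbre.

Two presets fix the axis conventions: *traditional* (frequency over rows,
increasing bottom→top; time over columns, left→right) and *reversed*
(frequency over columns, increasing left→right; time over rows,
top→bottom). They share every timing and frequency parameter, so the two
encodings of one image differ only by an axis permutation — the
transpose-plus-flip duality tested in the suite. Amplitude is linear in
brightness; the canonical stimuli are binary, so amplitude carries no
information there, but grayscale input is supported.

The *control* scheme maps each stimulus id to one constant pure tone over
the full sonification span. Tones are drawn uniformly over the feasible
set of the constraint "all in [f_min, f_max], pairwise ≥ 50 Hz apart" by
the order-statistics construction (draw k points uniformly in the
gap-reduced interval, sort, add `i · 50 Hz`, then randomly permute the
assignment to ids); the separation holds by construction and the closed
form `(f_max − f_min)/sep + 1` (= 91 on the default range) bounds the
feasible count.

## Decoding

The sonification span is `Σ_{r,c} b[r,c] · atom_{r,c}` with known atoms,
so decoding is linear estimation. Atoms in different time steps have
disjoint support; the global least-squares problem is block-diagonal and
is solved per step (64 unknowns against ~724 samples). On noiseless input
this is exact: residuals are at float precision (~1e−29 of signal
energy), and thresholding the max-normalised coefficients at 0.5 returns
every canonical stimulus bit-exactly under both presets.

Noise exposes a real ill-conditioning: near 500 Hz the log spacing
between adjacent oscillators (~18 Hz) is far below the ~61 Hz Rayleigh
resolution of a 16.4 ms gate, so within-step atom blocks have condition
numbers ~1e4 and plain least squares amplifies noise along the weak
singular directions by orders of magnitude. The decoder therefore
estimates the per-step noise power from the residual of the plain solve
(`σ̂² = ‖r‖²/(m−n)`) and, when it is non-negligible, re-solves with
Tikhonov-damped non-negative least squares, `λ = α·m·σ̂²` with `α = 3`
(`α` of order 1 balances shrinkage bias against noise suppression; the
damping vanishes identically on clean input, preserving the exact path).
Shrinkage alone still biases stroke-edge amplitudes below a fixed
threshold, so for near-binary sources a refinement exploits one more
constraint: all active pixels of a binary image share a single global
amplitude `a` (brightness 1 times the common normalisation). The decoder
estimates `a` from the top coefficient cluster, then minimises the exact
per-step residual over binary activation patterns by greedy descent using
single bit flips plus simultaneous pair flips (pairs are required because
nearly-collinear neighbouring atoms trade off together), alternating with
a global re-fit of `a`. This restores 100% bit-exact recovery of the
canonical bank at 20 dB SNR under both presets; below ~15 dB recovery
degrades gracefully (a few pixels on a few stimuli). The refinement
presumes a near-binary source and is on by default; pass
`refine_binary=False` when decoding grayscale material under noise.

Decoding is scale-invariant (coefficients are max-normalised, and the
noise estimate scales with the waveform), and quantisation noise from
16-bit WAV round trips (~90 dB SNR) is far inside the robust regime.
Decoding with a mismatched preset is supported and, by the axis duality,
returns the transposed-and-flipped image — useful as a negative control.

## Stimulus bank

Stimuli are explicit bitmaps, not font renderings, to guarantee bit-exact
fixtures across platforms: 16×16 templates in a packaged JSON manifest,
block-upscaled ×4 to 64×64. Rotation is the exact index permutation
`(r, c) → (c, n−1−r)` per clockwise quarter turn — a bijection, so pixel
counts are conserved and round trips are lossless; oblique angles are
rejected.

The canonical bank has 12 groups expanding to 39 variants: dot (1,
4-fold symmetric), two-dot pair PP (3), line D (2, 180°-symmetric), E
(4), H (2, 180°-symmetric), plus seven unnamed groups — six asymmetric
4-variant glyphs (L, T, F, U, J, P) and one 3-variant glyph (C). Group
identities beyond the five named ones are this package's choice,
constrained to reproduce every count (12 groups, 39 stimuli, named sizes
1/3/2/4/2). A subtlety: orbit sizes under cardinal rotation are
necessarily 1, 2 or 4, so a 3-variant group can only arise by *retaining
a subset* of a 4-element orbit. PP is therefore an off-centre asymmetric
dot pair with angles {0°, 90°, 180°} retained, and C likewise; the
`GlyphSpec` validator enforces pairwise-distinct declared variants and
reports (rather than forbids) partial orbits via `symmetry_closed()`.

The familiar/novel split draws 6 of 12 groups with the dot, two-dot and
line groups forced into the familiar set (they open the learning
sequence, dot+pair first, line second); the remaining three familiar
slots are seeded-uniform over the other nine groups.

## Protocol simulation

Learning: per familiar group, variants are presented in angle order then
reversed (E0 E90 E180 E270 E270 E180 E90 E0), the palindrome repeated
three times, followed by two probe questions drawn without replacement
from that group's variants (with replacement only for the single-variant
dot group, where two distinct probes are impossible); probe options are
all the group's variants (1–4). A probe allows up to three attempts; the
simulator removes a refused option after each wrong attempt (feedback
that an answer was wrong is implicit in being allowed another try), and
only attempt-1 correctness enters accuracy. The ordered group plan
(forced groups first, remainder seeded-shuffled once) is traversed twice.
Probes sample from the current group only; sampling from all groups
learned so far is a plausible alternative reading and can be composed
from the same primitives.

Evaluation: every stimulus in the bank is heard twice in fully random
order; each trial shows five images — the correct one, two drawn from the
familiar stimuli and two from the novel stimuli (heard excluded from the
distractor pools), so a familiar-heard trial shows 3 familiar + 2 novel
options and a novel-heard trial 2 + 3. No feedback. The canonical bank
yields 78 trials per session.

Agents: `random_guesser` (uniform over options; analytic accuracy 1/5),
`familiarity_gated` (classifies the heard soundscape's true category,
optionally with a configurable miss rate, then guesses uniformly within
that category's options; analytic accuracy 1/3 in both trial
compositions), and `template_observer` (renders each candidate image
under its trained mapping and picks the maximal normalised
cross-correlation of magnitude spectrograms against the heard soundscape;
frames are one time step, no overlap, matched to the encoding's time
resolution). The template observer with a matched mapping is an ideal
observer — all 39 soundscapes are pairwise acoustically distinct, so it
scores 100% on familiar and novel stimuli alike; trained on one mapping
and tested on another (`mismapped_observer`) it degrades, providing the
structured-vs-mismatched contrast at the agent level. Human latencies,
learning curves and confidence are deliberately not modelled; the exact
binomial tail (`above_chance_test`) is the only inferential statistic.

## What the simulations show — and do not

The synthetic agents bound the protocol analytically: 20% (uniform
guessing), 1/3 (category gating), 100% (ideal acoustic matching). They
are not models of human learners; in particular the Monte-Carlo chance
levels validate the *trial generator* and the *analytic chance
arithmetic*, not any claim about human performance, and the template
observer's perfect generalisation to novel stimuli shows only that the
encodings are information-preserving, not that humans can exploit them.
Human behavioural effect sizes are outside this package's scope.

## Sizes, seeds, tolerances

Monte-Carlo chance levels use 100 000 trials (Monte-Carlo standard error
≈ 0.13 percentage points at p = 0.2; assertions allow 3 SE). Control-tone
checks use 100 seeds × 39 tones. Round-trip exactness asserts residual
energy fraction < 1e−6 (measured ~1e−29) and zero pixel mismatches on all
39 stimuli × both presets. All stochastic components take explicit
integer seeds (NumPy `default_rng`); sub-seeds are spawned from one root
seed, and identical seeds give bit-identical waveforms, trial lists and
CSVs. Dictionary blocks warn above condition number 1e8 (the default
mapping peaks near 1.2e4).

## Known limitations

- The seven unnamed glyph groups are a faithful reconstruction of the
  bank's combinatorics, not of the exact printed shapes; the manifest is
  a drop-in replacement point.
- The equal-amplitude refinement assumes near-binary sources; grayscale
  decoding under heavy noise falls back to shrinkage-biased estimates.
- The single-tone control scheme models only the published constraint
  (unique tones ≥ 50 Hz apart); any perceptual-spacing subtleties of a
  deployed implementation are not reproduced.
- Stereo panning, larger matrices (176×64) and real-time capture are out
  of scope.
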