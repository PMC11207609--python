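# Methods

This note documents the models, conventions and numerical choices behind
`icufusion`, module by module, including what the synthetic generators do
and do not emulate.

## Observation model and code registry (`fhir_model`)

The in-memory record targets the R4 Observation shape restricted to seven
fields (category code, subject, effectiveDateTime, device type/location,
components with LOINC code / display / typed value / UCUM unit).  JSON is
the single serialization dialect, one observation per NDJSON line;
round-trip identity (`read(write(R)) == R`) is an invariant, which is why
decimals are serialized as JSON numbers at full precision and timestamps as
ISO 8601 with an explicit UTC offset — multi-device fusion needs an
unambiguous time order.  Range values serialize as `{"low", "high"}`.

The code registry ships as a versioned JSON asset covering the vital signs,
ventilator settings, blood gas tensions, hemodynamic outputs, hematology
counts and infusion rate used by the generators.  Only heart rate
(`8867-4`, `{beats}/min`) and arterial oxygen saturation (`2708-6`) are
universally fixed pairings; the remaining codes are best-effort mappings
from the public LOINC table and are flagged `external-standard` in the
asset.  Lookup of an unregistered name raises; there is deliberately no
silent default, because a miscoded observation is worse than a dropped one.

## Device dialects and translation (`protocol_translation`)

Three dialects are supported.  The HL7 v2 subset is MSH+OBX, pipe-delimited
with `^` components; OBX-3 carries the device's observation code, OBX-5 the
value, OBX-6 the unit, MSH-7 the device timestamp.  JSON payloads use
dot-separated key paths.  The proprietary grammar is fixed as
`LABEL<kv-delim>VALUE` tokens joined by a per-category field delimiter —
vendor documentation tables map directly onto this shape.

Mappings are compiled deterministically from registered device features: a
table-driven tokenizer, not a generated lexer, so the same registry always
produces identical rules.  The `compiled_at` field of the rules is a
content fingerprint rather than a wall-clock time for the same reason.
Policy decisions: out-of-range values are flagged and forwarded (clinical
extremes are signal, not noise); a missing patient identifier translates
with subject `UNKNOWN` plus a warning, since device streams can outpace
admission/transfer linkage; device-reported time wins over gateway receive
time when both exist (a convention — reconciliation is not otherwise
specified anywhere authoritative).

## Stream fabric (`stream_fabric`)

Topics are one-per-category (`Topic_PM`, `Topic_VEN`, `Topic_HIS`,
`Topic_AI`, ...), each with a configurable partition count (default 64).
Message keys map to partitions by a SHA-256-based stable hash.

Partition→node placement is balanced round-robin with minimal-move
rebalancing: on a node failure only the failed node's partitions move, and
they are re-spread one at a time onto the currently least-loaded survivors.
A hash-ring scheme was considered and rejected: consistent hashing only
balances to within O(1/√vnodes) and can violate a max/min load ratio of
1.5 with realistic partition counts, whereas round-robin placement
guarantees successive node loads differ by at most one partition while
preserving the same minimal-churn property on failure.  Durability is an
abstraction (replication factor ≥ 2 assumed): queues survive node failure,
and conservation — delivered count equals enqueued count whenever at least
one node survives — is the tested guarantee.  Byte-level replication,
consumer groups and exactly-once semantics are out of scope.

Throughput/storage aggregation uses decimal units (1 Mbps = 1000 Kbps,
1 TB = 1000 GB); the reference inventory's printed sums only reconcile
under decimal units.  `math.fsum` keeps totals exact and order-independent.
The hematology analyzer entry is taken as 7.2 Mbps; its source lists an
ambiguous double unit, and only the Mbps reading reconciles with the
65.66 Mbps net rate.

The delay simulator models one Poisson arrival stream (rate = topics ×
per-topic rate) routed uniformly across nodes, each node a FIFO server with
exponential service; waiting times follow the per-node Lindley recursion
`W_k = max(0, W_{k−1} + S_{k−1} − A_k)`.  Standard errors use batch means
(40 time-ordered batches) because sojourn times are autocorrelated in
queue.  At one node this is exactly M/M/1, so the mean sojourn is checked
against `1/(μ−λ)`.  Absolute millisecond delays of any real deployment are
*not* reproduced — the underlying service-time parameters are unpublished —
only the M/M/1 limit and the monotone improvement with node count.

## Clinical indices and alerts (`clinical_indices`)

Predicted body weight uses the ARDSNet/Devine form; heights below the
152.4 cm anchor floor at the base weight (50 / 45.5 kg) rather than
extrapolating negative increments.  The ventilatory ratio's default form is
`Ve·PCO2·Vt / (100·37.5·PBW)` with Ve in L/min and Vt in mL; the
conventional bedside index (Ve in mL/min, no tidal-volume factor) is
available as `mode="standard"`.  Both are kept because the default form's
tidal-volume factor may be a typesetting artifact of its source and no
worked value exists to disambiguate; the constants 100 (mL/kg/min predicted
minute ventilation) and 37.5 mmHg (ideal PCO2) are named module constants.

Alert boundaries are strict: LTVV fires above 8 (8.0 exactly is safe), P/F
below 300 (300 exactly is safe), FiO2 at or above 0.4 ("must be lower
than" 0.4).  FiO2 is a fraction in (0, 1] throughout the indices layer;
percent values arriving from devices are normalized during fusion.  Vital
normal ranges (HR 60–100, RR 12–20, SpO2 ≥ 94%, systolic 90–140) are
configurable conventions, not derived values.

Fusion is latest-value-within-window per parameter over time-sorted
observations, with per-field provenance (source observation index and
timestamp) and an explicit incomplete-state error listing missing fields —
a stale blood gas should block index computation, not silently reuse old
values.

## Cluster reliability (`reliability`)

Single-cycle model: each of I nodes fails once (exponential lifetime, mean
1/λ) and is repaired once (exponential duration, mean r); γ = r·λ.  The
cluster-failure event is "all I nodes down simultaneously at the last
failure instant t₍I₎" — by memorylessness of the repairs, the probability
is E[∏_{j<I} exp(−(t₍I₎−t₍j₎)/r)], and with independent exponential
spacings t₍k+1₎−t₍k₎ ~ Exp((I−k)λ) this evaluates to
∏_k (I−k)γ/((I−k)γ+k), which reduces exactly to γ/(1+γ) at I=2 and
2γ²/((2γ+1)(γ+2)) at I=3.  The Monte-Carlo simulator implements the timing
model directly (sort lifetimes, carry repairs along) and is the independent
check on the closed forms; the test suite compares them at 3 binomial
standard errors.  A conservative variant (`event="any_overlap"`, failure as
soon as any single repair overruns t₍I₎) is provided for comparison; it
upper-bounds the all-down probability.

On the γ orientation: with a mean lifetime of one year (8760 h = 365 days)
and γ = repair/lifetime, PF(3) = 10⁻⁶ solves to r ≈ 8.77 h, i.e. a
nine-hour repair deadline at whole-hour rounding; at exactly 9.00 h the
closed form gives ≈ 1.05 × 10⁻⁶, marginally above the target — the
deadline is a rounding of 8.77, not a hard bound at 9.  The opposite
orientation (γ = lifetime/repair) reproduces no such number, which is why
repair/lifetime is adopted.  Root-finding is monotone bracketing on log-γ
(bracket 10⁻⁹–10³) to below 10⁻⁹ relative tolerance; `max_repair_time` and
`pf_general` are mutual inverses to that tolerance.  Renewal (repeated
failure/repair) processes and non-exponential lifetimes are out of scope.

## Stage graph and ensemble (`ards_automl`)

A stage graph is validated before use: inputs must resolve against earlier
stages or same-stage predecessors already evaluated, outputs are unique, a
node may not consume its own output, and exactly one label column is
flagged.  Built-in nodes call the `clinical_indices` functions row by row,
so their outputs are bit-identical to direct calls — extraction must never
introduce a second implementation of a clinical formula.  User expressions
are a restricted arithmetic mini-language (`+ − * /`, parentheses, names,
numeric literals) evaluated through a whitelisted AST walk instead of
embedded scripts: sandboxed and testable.

The ensemble trains SVM, XGBoost and MLP (library-default hyperparameters,
recorded in the run manifest) on a stratified split, default 80/20.
Majority voting fuses hard labels, ties in even-member votes breaking
toward the ARDS class (clinically conservative, warned).  AUC is always
scored on averaged member probabilities, because a three-member vote
fraction takes only four values and destroys the ranking the metric needs;
label-type metrics (F1, precision, accuracy) score the fused labels.
Probability averaging is the second implemented fusion rule; boosting,
bagging, stacking and blending are declared extension points.

## Synthetic data (`synthgen`)

The generators define the study conditions for all tests.

*Cohorts*: sex-specific Gaussian heights (171 ± 7 / 158 ± 7 cm) truncated
to the 120–230 cm validity range; ward-zone mix 20/20/60% negative-pressure
/ contact-isolation / regular.  These are realistic adult-ICU conventions;
no authoritative patient distributions exist to copy.

*Streams*: per-category byte budgets proportional to the reference rates
(29.7 : 26.1 : 2.32 : 0.344 : 7.2), with a recorded scale factor (default
20 000 bytes per Mbps-unit ≈ 1.3 MB per corpus) and device counts at one
tenth of the reference inventory.  The ratios, not the absolute rates, are
the preserved quantity — a desk run cannot and should not move 65 Mbps.
Patient monitors emit HL7 v2, infusion pumps JSON, the rest the proprietary
dialect; every message parses against the shipped registries with zero
errors (tested).  No waveform content is synthesized.

*ARDS tables*: the label mechanism is a two-component Gaussian model on a
latent P/F ratio — class means `255 ± effect/2` mmHg, within-class SD 45,
prevalence 0.3 — which is *exactly* a logistic model on the latent P/F
with coefficient `−effect/45²` (the linear-discriminant identity), so the
mechanism is recoverable by logistic regression (tested to 15% relative
error at n = 20 000).  Measurement noise (default SD 30 mmHg) enters the
observed P/F before PO2 is scaled by an independently drawn FiO2 ~
U(0.4, 1.0); consequently the Bayes-optimal classifier given the observed
features ranks by observed P/F and its AUC has the closed form
Φ(effect / √(2·(45² + noise²))) ≈ 0.975 at the default effect of 150 mmHg.
Defaults (n = 2000, effect 150, noise 30, prevalence 0.3) describe a
clearly separable but noisy oxygenation signal.  What passing tests show:
the extraction/training scaffold works end to end and recovers a planted
signal.  What they do not show: performance on hospital data, where the
label is a clinical adjudication, features are correlated and
missingness is informative; the independent-FiO2 assumption in particular
is a deliberate simplification (real FiO2 is titrated to oxygenation).

*Worked case*: a fixed, seedless two-point trajectory.  The target indices
(LTVV 10.0, P/F 164, FiO2 1.0; later LTVV 6.1, P/F 320, FiO2 0.35) fix
only ratios, so the inputs (Vt 600 mL, PBW 60 kg, PO2 164 mmHg; later
Vt 366 mL, PO2 112 mmHg) are reverse-engineered and documented as
constructed.  The profile height (163.4 cm) gives a Devine PBW of ≈ 60 kg;
the states carry PBW = 60 exactly so the derived indices are exact.

## Problem sizes

Defaults were chosen so the full suite and the acceptance script each run
in well under a minute on one CPU: Monte-Carlo reliability at 4 × 10⁵
replications in unit tests and 10⁶ in the acceptance script (binomial SE
≈ 9 × 10⁻⁵ at PF3 = 0.0079, ample for 3-SE agreement), queueing runs of
1.2–1.5 × 10⁵ messages, ensemble training at n = 2000 over five seeds, and
mechanism recovery at n = 20 000.
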