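# Methods

This note documents the models, numerical choices and known limitations of
`neuroloop`, in the order data flows through the system.

## Stream bus

Inter-node communication uses append-only streams with per-stream ids that
start at 1 and increase by 1 per append under a store-wide lock, so total
order per stream holds for any interleaving of writers. Two backends share
one contract: an in-process store (threads in one process) and a socket
server speaking a length-prefixed binary protocol with XADD/XREAD-equivalent
commands over TCP or Unix sockets for multi-process graphs. All numeric
fields are little-endian. The write timestamp is taken from
`time.monotonic_ns()` immediately before the write call and carried *inside*
the entry (field `_ts`), so latency arithmetic between nodes on one host
uses a single clock domain; cross-host clock reconciliation is out of scope
(the runtime is single-host). Streams grow without bound by default so a
session retains its complete log; a ring-buffer trim (`max_stream_length`)
is available for long benchmarks. The bus is intended for trusted local
use; it has no authentication, like the in-memory stores it stands in for.

## Graph runtime

Graphs are described by one YAML document (`graph_name`, `nodes`, optional
`bus` and `external_streams`). Validation enforces: at least one node,
unique nicknames, resolvable executables, every input stream produced by
some node or declared external, and — a deliberate strengthening — **one
writer per stream**, which makes per-node latency attribution well-defined.

Node lifecycle: the supervisor writes each node's parameter entry to
`ctl:<nickname>` *before* spawning the process, so parameters always precede
the run loop; the node host publishes `initialized`, waits for `go`, runs
with a 1 s heartbeat on `status:<nickname>`, and exits on `stop` (graceful
window 2 s, then forced kill, flagged in the final status). A process that
exits without having been told to stop is reported `crashed`; crashed nodes
are not restarted. Priority requests map to Unix niceness and degrade to a
warning without privilege; affinity uses `sched_setaffinity`.

The parallelism property (a slow downstream node must not perturb publisher
pacing, while an equivalent sequential program falls behind) is asserted in
the test suite at 200 Hz with a 10 ms downstream stage over ~2 s runs —
sizes chosen so the property is unambiguous on a single-core machine — with
a sequential single-process reference implementation for contrast.

## Neural simulator

Firing rates follow rectified cosine tuning,
`λᵢ = max(0, b₀ᵢ + mᵢ (v·pᵢ)/v_s)`, with defaults b₀ = 10 sp/s, m = 40 sp/s,
preferred directions uniform on the circle, and `v_s` equal to the nominal
movement speed so a full-speed movement along `pᵢ` yields b₀+m. Spike
generation is Poisson per 1 ms window (counts > 1 allowed) — the minimal
point-process model, chosen because nothing finer is needed downstream.
Each spike inserts a biphasic template (sharp −80 µV trough at ~0.25 ms, 35%
positive rebound, 1 ms long) at a uniformly random sub-millisecond offset
over white Gaussian noise of 10 µV RMS; template tails are carried across
block boundaries, and output is clipped to int16. The defaults give an 8×
peak-to-noise ratio so −3.5×RMS detection is exercised realistically.

Packets use a documented emulated layout (header: `seq u32, C u16, S u16,
timestamp u64`, then C·S int16 LE), honouring the acquisition-hardware
*semantics* — 1 ms per packet, 30 samples/channel at 30 kHz, sequence
counter — without any vendor byte format. The parser tracks sequence gaps
and reordering.

What the simulator does **not** model: electrode drift, waveform variability
and multi-unit overlap on a channel, correlated or non-Gaussian noise, LFP
content, and any adaptation of tuning over time. Tests passing on this
generator therefore validate the pipeline's signal path and the estimators'
correctness, not robustness to real recording pathologies.

### Tuning-parameter recovery

`recover_tuning` refits each channel's (b₀, m) from 1 ms Poisson counts by
per-channel Newton iteration on the identity-link Poisson likelihood,
masking samples whose fitted rate is below 0.5 sp/s (near the rectification
point the identity-link weights diverge), initialized by least squares on
the positive-drive half where the rectified curve is exactly linear.
`tuning_recovery_experiment` pairs this with an information-motivated
velocity design: two-thirds of the time at rest (pinning b₀) and one-third
in constant-speed direction sweeps at 3× the full-modulation speed (pinning
m). Precision is bounded by counting statistics — with b₀ = 10 sp/s and
60 s of data, se(b₀) ≥ √(10/60) ≈ 4.1% of b₀ *for any design* — so the
estimator operates at the Cramér–Rao bound and per-channel errors of a few
percent are the floor, not an implementation artifact. The recovery study
uses 4 channels.

## Signal chain

* **CAR**: per time sample, subtract the cross-channel mean; exact zero
  column means; idempotent; disabled by default (toggleable node).
* **High-pass**: 4th-order Butterworth, 250 Hz, applied forward-backward
  (`sosfiltfilt`) over a sliding 4 ms buffer; only the newest millisecond is
  emitted, which minimizes added latency. The buffer is zero-padded at
  session start (first 3 ms are warm-up). Multi-millisecond input is
  filtered by stacking all sliding windows into one batched call, which is
  numerically identical to stepping 1 ms at a time. Note the emitted
  millisecond sits at the window edge, where the zero-phase pass leaves a
  slightly heavier-tailed residual than the ideal frequency response
  implies; passband checks therefore use RMS amplitude.
* **Thresholds**: per-channel −3.5 × RMS, RMS estimated from the first 10 s
  of filtered session data (configurable) and frozen. A crossing is a
  *downward* edge — `x[k] ≤ θ` with `x[k−1] > θ` — with the previous
  block's last sample retained so boundary-spanning events count exactly
  once; at most 30 events/ms by construction. Under the Gaussian noise
  model, tail events produce a false-crossing floor of several events per
  second per channel at −3.5σ; the test suite therefore verifies the exact
  accounting identity (detected = injected + independently measured false
  alarms, within counting statistics) rather than pretending false alarms
  do not exist.
* **Spike-band power**: mean of squared filtered samples per 1 ms window.
* **Binning**: 10 consecutive 1 ms frames per bin; crossings are *summed*
  (count semantics), power is *averaged* (power semantics); missing frames
  zero-fill and are flagged. Feature vector order is
  `[crossings(1..C), sbp(1..C)]` — 384-dim for 192 channels.
* **Normalization**: z-score per feature against the most recent completed
  calibration block; `ε = 1e-6` guards constant features.
* **Acquisition merge**: multiple packet sources align by sequence number
  (two 96-channel sources → 192-channel frames); a missing packet yields a
  zero-filled slice and a gap count rather than a stall.

## Decoders

**OLE.** Closed-form ridge with the intercept left unpenalized (via
centering). The penalty is selected from 10 log-spaced values in
[1e−3, 1e3] by 3-fold cross-validation on *contiguous temporal thirds* —
shuffled folds would leak autocorrelated neighbours between train and
validation. λ = 0 is skipped with a warning on rank-deficient designs.
Features may be crossings-only (C) or crossings+power (2C).

**Recurrent decoder.** One LSTM layer (76 units default) with forget-gate
bias 1, uniform ±1/√fan-in init, a 2-unit linear readout, mean-squared-error
loss, full-batch BPTT with Adam (lr 3e−3), optional inverted dropout on the
hidden state before the readout and L2 on the weight matrices; at most 50
epochs with plateau early-stopping (patience 8, tol 1e−5). Implemented in
NumPy; gradients are verified against central finite differences in the
test suite, and stateful single-step inference is exactly equal to batch
inference. Training is deterministic given the spec seed. It consumes
crossings-only features normalized by the training data's own statistics.
Hyperparameter search is out of scope; the defaults above are fixed.

**Smoothing and gain.** `s_t = α v_t + (1−α) s_{t−1}`, output `g·s_t`, with
α = 0.3 and g = 1.0 in simulation configs (free parameters, exposed in
YAML). **Intent relabeling** for retraining points the vector from cursor to
target, scaled to the decoded prediction's magnitude, zeroed once the cursor
is inside the target radius (no hold requirement — relabeling and
acquisition deliberately use different predicates).

## Task

Radial-8 center-out-and-back: 8 ring targets at 45° spacing alternating
with the center. Defaults (not derivable from prior art, chosen as a
sensible desk-scale geometry): workspace [−0.5, 0.5]², ring radius 0.4,
target radius 0.05, hold 300 ms, timeout 10 s, 10 ms ticks. The cursor
integrates decoded velocity by explicit Euler and clamps to the workspace.
Acquisition requires continuous residence for the hold time; timeout logs a
failure and advances. The autopilot moves at `min(speed, distance/dt)`
toward the target (no overshoot), with a nominal speed of 0.8 units/s.

In closed-loop simulation the participant's *intent* is modelled as
autopilot velocity toward the active target — the analog of the cooperative
user the cursor-control simulator is driven by — while the cursor itself
moves only as the decoder commands. This closes the loop through the
tuning model without assuming anything about the decoder.

## Sessions

The default protocol mirrors a standard calibration session scaled down 6×
for desk-scale runs: 30 s open-loop calibration (plus 10 s threshold
calibration at rest), 40 s of OLE closed-loop control (whose data, intent-
relabeled, trains the recurrent decoder), then 40 s of recurrent-decoder
control. Archives are self-contained (per-stream binary logs + JSON index,
decoder files annotated with the indices of the blocks that trained them,
trial logs as CSV) and reload bit-exactly. Accelerated (as-fast-as-possible)
replay produces streams identical to real-time pacing except for embedded
timestamps.

## Latency benchmarking

Publisher→forwarder→subscriber chains; every node samples the monotonic
clock immediately before its stream write, and hop latency is the
difference of consecutive write timestamps for the same packet. Publisher
pacing uses absolute deadlines (`start + k/rate`), not fixed sleeps, to
avoid drift. The median uses the even-sample midpoint rule; p90/p99 are
nearest-rank order statistics; lost or clock-anomalous records are excluded
from statistics but always counted. Forwarders re-serialize payloads rather
than passing references, so every hop pays the full encode/write cost.
Benchmark nodes run as threads over the shared bus by default (the graph
runtime can run the same nodes as separate processes over a socket bus);
absolute latency numbers depend on host, scheduler and kernel configuration
and are *reported, not asserted* — real-time kernel tuning (e.g.
PREEMPT_RT) is documented as an option for deployments, not performed here.

## Problem sizes in the test and acceptance runs

Full study conditions — 96 channels, 30 s calibration, 16 radial-8 trials,
60 s recovery data, 60 s of 1 kHz 192-channel stream traffic — are
exercised in the acceptance suite and `scripts/acceptance.py`. Unit and
integration tests run the same procedures at reduced scale (8–32 channels,
seconds-long blocks), sizes chosen so each property is still decisively
testable: e.g. the open-loop decode correlation exceeds 0.8 from 32
channels upward, and detection accounting uses 20 s at 8 channels for
~2000 ground-truth spikes per channel.

## Known limitations

* Single host, single clock domain; no multi-machine orchestration.
* The supervisor does not restart crashed nodes.
* The bus is unauthenticated and in-memory; persistence is the session
  archive, not the store.
* The simulator's noise and waveform models are deliberately minimal (see
  above); closed-loop success rates on simulated data say nothing about
  human performance.
* The recurrent decoder trains full-batch on CPU; it is sized for
  minutes-scale sessions, not large offline corpora.
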