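# cbgt — dual-competition cortex–basal-ganglia–thalamus decision model

`cbgt` is a firing-rate simulator of decision making in closed
cortico-basal-ganglia-thalamic loops, built for studying **covert
learning**: the striatum keeps learning cue values under dopaminergic
control even when the basal-ganglia output is blocked and behaviour is
random, and the stored values surface as an immediate performance jump the
moment the output is restored.  It is aimed at computational
neuroscientists who want a compact, fully tested model of action selection
with two interacting decision systems — a reward-driven basal-ganglia
competition and a reward-blind Hebbian cortical competition.

## The model in brief

Twelve rate-coded populations (cognitive, motor and associative loops; 72
assemblies) obey

    τ dV/dt = −V + I_syn + I_ext + h,        U = f(V + V·n),

with ramp transfer everywhere except the striatum, which uses a Boltzmann
sigmoid f(x) = V_min + (V_max − V_min)/(1 + e^{(V_h − x)/V_c}).  Decisions
emerge from a race read out in motor cortex (40 spikes/s difference
criterion) and are shaped by two competitions: the direct/hyperdirect
basal-ganglia pathways (disinhibition gate through GPi and thalamus) and
lateral cortical interactions (short-range excitation, long-range
inhibition).  Two plastic pathways, both cognitive, learn after every
trial: cortico-striatal synapses via an actor–critic rule
(ΔW = LTP_RL·RPE·U_B for RPE > 0, LTD_RL·RPE·U_B for RPE < 0, with
RPE = R − V_i and V_i ← V_i + α·RPE) and cortico-cortical synapses via pure
Hebbian coactivity (ΔW = LTP_HL·U_A·U_B), all under a soft-bounding map
that confines weights to [0.25, 0.75].  The model's parameters, the
two-armed bandit task (P = 0.75 / 0.25), the GPi-lesion protocol and the
rank-based statistics are described in [docs/methods.md](docs/methods.md).

## Worked example

Run the covert-learning experiment — 12 independently seeded sessions of
C0 (intact), C1 (GPi output cut), C2 (output restored, carrying C1's
weights and critic values) — and analyze it:

```python
from cbgt import run_covert_learning_protocol, analyze_protocol

result = run_covert_learning_protocol(n_sessions=12, master_seed=0)
print(result.summary().round(3).to_string(index=False))

report = analyze_protocol(result, alpha=0.01)
H, p = report["kruskal"]
print(f"Kruskal-Wallis: H = {H:.1f}, p = {p:.3g}")
print(report["planned"].round(4).to_string(index=False))
```

prints

```
condition window  mean    sd  n_sessions  n_pooled
       C0  start 0.517 0.170          12       120
       C0    end 0.708 0.162          12       120
       C1  start 0.492 0.124          12       120
       C1    end 0.525 0.218          12       120
       C2  start 0.708 0.108          12       120
       C2    end 0.833 0.115          12       120
Kruskal-Wallis: H = 49.7, p = 1.59e-09
                 H0  statistic  p_adj  significant  n_per_sample
C0_start = C2_start     3.0739 0.0045         True           120
C1_start = C2_start     3.4748 0.0015         True           120
  C1_end = C2_start     2.9402 0.0055         True           120
```

Read it as the covert-learning signature: with the GPi output cut (C1) the
model chooses the richer cue at chance, start (0.492) and end (0.525)
alike — yet when the output is restored (C2) performance starts at 0.708,
above both, and every planned comparison clears adjusted p < 0.01.  The
head start comes entirely from the cortico-striatal weights and critic
values learned silently during C1: resetting them before C2
(`carry_c1_to_c2=False`) puts the C2 start back at chance.

The same experiment from the shell, with per-session trial logs, summary
and stats CSVs:

```bash
cbgt simulate --protocol covert --sessions 12 --seed 0 --out runs/demo/
cbgt analyze --in runs/demo/ --alpha 0.01 --out runs/demo/report.csv
cbgt figures --what dynamics --out runs/demo/
```

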