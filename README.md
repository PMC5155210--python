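# targetspread

Identify influential spreaders **toward a localized group of target nodes**
in a network.

Most influence rankings (degree, betweenness, k-shell) answer the global
question — *which node would infect the most nodes?* — and routinely point
at hubs that are topologically far from a particular target group. In many
applications (advertising to a specific audience, circulating a job posting
to one research community, reaching one module of an interactome) the
spreading only needs to reach a small, spatially concentrated set of
targets, and should ideally avoid everyone else. `targetspread` implements
the **reversed local path (RLP)** ranking for this problem, the baseline
centralities it is compared against, a discrete-time SIR simulator, and
the evaluation harnesses that measure how well each ranking predicts true
targeted spreading ability.

## The RLP score

Let *A* be the adjacency matrix of the undirected network and *f* the 0/1
row indicator of the m target nodes. The RLP score of node *j* is

```
s(j) = Σ_{l=0}^{K−1} ε^l · (f A^{l+1})_j        (defaults: K = 3, ε = 0.1)
```

an ε-discounted count of walks of length 1..K *from the target set* to
*j*. Counting from the targets outward ("reversed" relative to the actual
spreading direction) costs O(m·k³) instead of O(N·k³); nodes farther than
K hops from every target score exactly zero. Spreading ability is measured
with the SIR model (per-contact infection probability λ, recovery
probability 1): ρ_i is the mean fraction of targets recovered when node
*i* seeds the epidemic, v_i the mean fraction of non-targets recovered,
and rankings are scored by the Kendall tau between method scores and
simulated ρ over all candidate (non-target) seeds.

## Worked example

```python
import numpy as np
import targetspread as ts

rng = np.random.default_rng(7)
net = ts.generate_ws(500, 4, 0.1, rng)          # small-world net, <k> = 4
lam_c = ts.hmf_critical_lambda(net)             # mean-field SIR threshold
targets = ts.place_localized(net, m=30, L=4, rng=rng)

sir = ts.SIRParams(lam=lam_c, n_realizations=100, rng_seed=7)
for method in ("rlp", "degree", "betweenness", "local_degree"):
    scores = ts.SCORERS[method](net, targets)
    tau = ts.rank_accuracy(net, targets, scores, sir)
    print(f"{method:>12}  tau = {tau:+.3f}")
```

prints

```
         rlp  tau = +0.526
      degree  tau = +0.082
 betweenness  tau = +0.213
local_degree  tau = +0.411
```

Near the epidemic threshold (λc ≈ 0.32 for this graph), the walk counts
from the target set predict the simulated targeted spreading ability far
better (τ ≈ 0.53) than the global centralities (τ ≈ 0.1–0.2), and better
than the distance-truncated local degree (τ ≈ 0.41): RLP weighs *how many
short routes* lead from the target group to a candidate seed, not just
whether the seed is nearby or well connected. (This is a single target-set
draw at R = 100 realizations per seed; the benchmark sweeps in
`scripts/acceptance.py` average many draws.)

The same operations are available from a CLI:

```bash
targetspread generate --model ws --n 500 --seed 7 --out ws.edgelist
targetspread score --network ws.edgelist --method rlp \
    --place-mode localized -m 30 -l 4 --seed 7 --out scores.csv
targetspread simulate --network ws.edgelist --seed-node 17 \
    --targets targets.txt --lam 0.32 --reps 500 --rng 7
targetspread experiment --config experiment.yaml --out-dir results/
```

`experiment` runs any of the four harnesses (`tau_vs_lambda`, `tau_vs_mL`,
`tradeoff`, `coverage`) from a YAML config and writes a tidy CSV plus a
manifest with every resolved seed; identical configs reproduce identical
bytes.

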