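# demeflow

Multilayer social-network modules and deme inference from RFID nest-box
records.

## The problem

Semi-natural enclosure studies of house mice monitor every entry to and exit
from each nest box with paired transponder antennas, producing months of
reader events per population. Two individuals that repeatedly rest in the
same box at the same time are socially associated; clusters of such
individuals — *modules* — that persist over weeks, monopolize boxes, and
contain the breeding pairs are candidate *demes*, the elementary
reproductive units of mouse populations. `demeflow` is the analysis pipeline
for this inference, for behavioural ecologists working with RFID
co-occupancy data:

1. **preprocess** — pair dual-antenna signals into credible visits, censor
   enclosure checks (to the following midnight), cut the record into time
   layers (≤ 48 h fragments with no gap > 1 h, short layers merged), detect
   inter-enclosure migrations;
2. **layers** — per layer, the weighted graph of pairwise co-occupancy
   seconds;
3. **mapeq** — couple the layers into one state network with a relax rate
   *r* and minimize the two-level map-equation codelength *L* with a
   Louvain-style search. Modularity is the compression rate
   **M = L_before / L_after** (one-module codelength over partitioned
   codelength, M ≥ 1);
4. **selection** — choose *r* by NMI consensus over a 21-value grid and test
   robustness with a visit-reordering bootstrap that conserves every
   individual's per-box time budget exactly;
5. **metrics** — module distinctiveness, spatial-separation index, box
   occupancy, period-summary networks;
6. **parentage** — multiple paternity, persistence of family bonds within
   modules, and per-module *deme support*: the effective number of parental
   pairs whose gestation period (conception = delivery − 20 d) was spent,
   by both parents, in the module where conception occurred;
7. **simulate** — a synthetic enclosure (communal co-nesting with planted
   modules, births, paternity skew, emigration, check schedules) so the
   whole pipeline is testable end to end without animal data.

## Worked example

```python
import demeflow as dm
from demeflow.pipeline import preprocess_events, cluster
from demeflow.parentage import build_litters, deme_support, multiple_paternity

cfg = dm.SimConfig(duration_days=45, mixing=0.05, conception_rate_per_day=0.2)
sim = dm.simulate_run(cfg, seed=1)
pre = preprocess_events(sim.events, sim.checks)
part, res = cluster(pre.networks, r=0.6, seed=1)
litters = build_litters(sim.pedigree, cfg.gestation_days)
support = deme_support(litters, part, pre.layers)
```

prints (via the obvious f-strings):

```
28208 reader events -> 6008 visits in 18 time layers (232 equivocal signals dropped)
M = L_before/L_after = 8.135/7.036 = 1.156 with 4 modules
NMI against the planted modules: 0.710
layer 3: distinctiveness = 0.969, spatial separation = 0.948
9 litters, multiple paternity = 0.000
module 0: effective pairs = 4.33, deme = True
module 1: effective pairs = 3.78, deme = True
module 2: effective pairs = 0.00, deme = False
module 3: effective pairs = 0.00, deme = False
```

Reading it: the two planted founder modules are recovered and carry all the
reproduction (effective pairs ≈ 4 each, so they are demes), while modules 2
and 3 are transient clusters of newly weaned pups — new vertices entering
the record often seed short-lived modules — and earn no deme support. The
NMI of 0.71 against the planted truth reflects exactly those pup cohorts:
ground truth labels pups with their mother's module for life, the clustering
is free to give them their own. Distinctiveness 0.97 says individuals spent
97 % of their interaction time with members of their own module in that
layer; spatial separation 0.95 says boxes were almost module-exclusive.

The same stages are scriptable from a shell:

```sh
demeflow --seed 7 --out-dir run simulate --duration-days 45
demeflow --seed 7 --out-dir run preprocess run/events.csv --checks run/checks.csv
demeflow --seed 7 --out-dir run cluster --visits run/visits.csv --layers run/layers.json -r 0.6
demeflow --seed 7 --out-dir run metrics --visits run/visits.csv --layers run/layers.json --partition run/partition.csv
demeflow --seed 7 --out-dir run parentage --pedigree run/pedigree.csv --partition run/partition.csv --layers run/layers.json
demeflow --out-dir run report
```

`cluster --scan` additionally scans the 21-value relax-rate grid and picks
the NMI-consensual value.

See `docs/methods.md` for the models, parameter defaults, numerical choices
and limitations.

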