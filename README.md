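# aedcorridor

Optimal deployment of automated external defibrillators (AEDs) in long,
narrow public spaces — trains, station platforms, tunnels, corridors —
modelled as a finite one-dimensional row of unit cells.

## The model

Survival after an out-of-hospital cardiac arrest (OHCA) depends sharply on
how quickly a defibrillator arrives. Around each AED the corridor splits
into three zones by acquisition time *t* (minutes, rounded up):

* **hot** (*t* ≤ 1): the device arrives within the window giving the best
  survival chance;
* **warm** (1 < *t* ≤ 8): it arrives before the average emergency-services
  response, with benefit decaying like 1/*t*;
* **cold** (*t* > 8): waiting for EMS is faster, so the AED contributes
  nothing.

For a set of AEDs the hot zone is the union of individual hot zones, the
cold zone the intersection of cold zones. With per-cell OHCA density
p(i) and cell area dA, the **rescue benefit** is the triple

```
A_H = Σ_{hot i}  p(i) · dA
A_C = Σ_{cold i} p(i) · dA
A_W = Σ_{warm i} (1 / t_i) · p(i) · dA
```

compared lexicographically: larger A_H, then smaller A_C, then larger A_W.
Three AED types differ only in acquisition time: **F** (fixed, fetched at
walking speed), **S** (summonable, delivered on call in half the time), and
**P** (patrolling, a summonable unit averaged uniformly over its patrol
range). All arithmetic is exact (`fractions.Fraction`), so zone sizes and
tie-breaks never suffer floating-point ambiguity.

The package provides:

* exact benefit evaluation for any deployment, density, and per-cell
  transport time (`aedcorridor.benefit`);
* exhaustive search over all placements of an inventory, returning every
  tied optimum (`aedcorridor.search`);
* the closed-form placement rules — center placement, 1-to-2 segment
  division for mixed fixed/summonable fleets, edge placement flanking a
  patroller — and a harness verifying them against the search
  (`aedcorridor.rules`);
* a synthetic scenario generator and a small CLI.

## Worked example

One fixed AED at cell 11 of a 22-cell corridor (1 minute per cell):

```
$ aedcorridor evaluate --length 22 --deployment F@11
deployment: F@11
A_H = 3 (3)
A_C = 5 (5)
A_W = 481/140 (3.43571)
CCWWWWWWWHHHWWWWWWWCCC
..........F...........
```

Three cells are hot (the AED's cell and its neighbours), five are cold
(two on the left edge, three on the right), and the fourteen warm cells
contribute 2·(1/2 + 1/3 + ... + 1/8) = 481/140. The map prints one zone
letter per cell with unit markers underneath.

Exhaustive search for the best single summonable unit:

```
$ aedcorridor optimize --length 22 --inventory 0,1,0
evaluated 22 deployments
best: A_H=5, A_C=0, A_W=53/10
  optimal: S@11
  optimal: S@12
```

The rule-based deployment for two fixed + one summonable + one patroller
(`rules`), and a rule-vs-search verification sweep (`verify`), round out the
CLI; `verify` exits non-zero if any rule deployment misses the exhaustive
optimum and can write the full comparison table as JSON or CSV.

Library use mirrors the CLI:

```python
from aedcorridor import (Deployment, Inventory, deployment_benefit,
                         exhaustive_optimal, fixed_at, make_corridor)

corridor = make_corridor(22)                      # defaults: τ=1, 1/8 min thresholds
triple = deployment_benefit(Deployment((fixed_at(11),)), corridor)
# BenefitTriple(hot=3, cold=5, warm=481/140)
result = exhaustive_optimal(corridor, Inventory(n_fixed=1))
# optimal plateau: F@9 ... F@14, same triple
```

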