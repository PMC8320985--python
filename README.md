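# eorscode

Construction and validation of constrained DNA codeword sets for data
storage and barcoding. A code here is a set of fixed-length words over
{A, C, G, T} in which

- every unordered pair differs in at least `d` positions (Hamming distance),
- every word carries an exact GC weight `w` (default `n // 2`), and
- no word contains a homopolymer run (no identical adjacent bases).

Two construction routes are provided and cross-checked:

- **Heuristic (EORS)** — an equilibrium-optimizer population search over
  continuous "concentration" vectors decoded to DNA words, followed by a
  random-search pass that inserts compatible candidates and swaps out single
  conflicting members.
- **Exact oracle** — exhaustive enumeration of all valid words, construction
  of the compatibility graph (edges join words at distance ≥ d) and exact
  maximum-clique search by branch and bound with greedy-colouring bounds.
  A code set is precisely a clique in this graph, so the clique number is
  the true optimum on small instances.

A 26-word published reference code (n = 9, d = 6, w = 4) ships as an
embedded fixture, together with published lower-bound tables used by the
benchmark harness.

## CLI

```sh
# full pipeline: EO stage then random-search augmentation
eorscode search -n 6 -d 3 --pop-size 50 --iterations 500 \
    --budget 100000 --seed 42 --out code.txt --summary run.json

# exact optimum (small instances only)
eorscode exact -n 4 -d 3

# enumerate every valid word for a profile
eorscode enumerate -n 4 -w 2

# validate a word list (plain text or FASTA) against a profile
eorscode validate code.txt -n 6 -d 3

# coding rate log4(M)/n
eorscode rate -M 110 -n 8

# sweep an (n, d) grid
eorscode benchmark --n-values 4,5 --d-values 3 --methods greedy,exact --seed 0
```

Word lists are plain text (one word per line, `#` comments) or FASTA
(`.fa`/`.fasta`, records `cw_0001`…). `--digits` writes the quaternary digit
form (T=0, C=1, G=2, A=3). `search --config cfg.yaml` reads option defaults
from a YAML mapping; explicit flags win. Runs are fully reproducible from
the master `--seed`.

## Python API

```python
from eorscode import (ConstraintProfile, eors_search, EOParams, RSParams,
                      build_conflict_graph, max_clique_exact)

profile = ConstraintProfile(n=6, d=3)           # w defaults to n // 2
result = eors_search(profile, EOParams(t_max=500), RSParams(budget=100_000),
                     seed=42)
print(len(result.final_set), result.final_set.coding_rate())

exact = max_clique_exact(build_conflict_graph(ConstraintProfile(n=4, d=3)))
```

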