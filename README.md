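# ptimebox

Probabilistic timebox queries over gene-expression time courses.

A *timebox* is a rectangle in (time, value) space: a deterministic query
keeps exactly the courses whose values stay inside every box at every
covered time point. That all-points-inside rule is brittle — a single
outlier, missing value, phase shift or speed change excludes a course.
`ptimebox` reinterprets an ordered set of timeboxes as a left-to-right
hidden Markov model:

* each box becomes a state with a **normal emission** (mean = box vertical
  midpoint, sd = quarter of the box height, so the box spans mu ± 2 sd,
  ≈ 95.5% of the emission mass) held for a **geometrically distributed
  duration** whose expectation is the box width
  (self-transition probability `p = 1 − 1/duration`);
* time spans with no box — gaps between boxes and the margins before the
  first / after the last box — get waiting states with a **uniform
  emission** over the data's value range;
* expected durations are normalized to sum to the course length `T`
  (floor 1.0 per state, clamp-and-redistribute).

Courses are scored with the forward algorithm (log-space, `O(K·T)` per
course) and the query answer is the `m` top-ranked courses. The classic
deterministic query is included for direct comparison.

## Data formats

* **Matrix**: delimited text (tab by default); first row = time labels,
  first column = course ids, `NA` (configurable) for missing values.
* **Query**: JSON or YAML, e.g.

  ```json
  {"mode": "probabilistic", "m": 150,
   "boxes": [{"t_lo": 1, "t_hi": 2.5, "x_lo": 0.5, "x_hi": 3}]}
  ```

  Box time coordinates are continuous on the 1-based index axis `1..T`;
  boxes must be ≥ 1.0 wide, have nonzero height, lie inside `[1, T]` and
  be time-disjoint (abutting edges are fine).

## CLI

```sh
# generate a synthetic matrix with planted signal courses
ptimebox simulate --config gen.yaml --out data.tsv --truth truth.tsv

# drop courses with many NAs or little expression change
ptimebox filter --data data.tsv --out kept.tsv --max-missing-fraction 0.25 --min-range 1.0

# inspect the compiled model
ptimebox compile --query q.json --data kept.tsv --out model.json

# run a query (probabilistic: ranked TSV; deterministic: one id per line)
ptimebox query --query q.json --data kept.tsv --m 150 --out result.tsv
ptimebox query --mode deterministic --query q.json --data kept.tsv
```

`gen.yaml` holds the generator settings (`n_signal`, `n_background`, `T`,
`segment_means` as `[length, level]` pairs summing to `T`, `noise_sd`,
`outlier_prob`, `outlier_magnitude`, `max_shift`, `speed_jitter`, `seed`).
Runs are deterministic given identical inputs and seed; use `-v` for an
audit log (input checksums, parameters, version).

## Python API

```python
import ptimebox as ptb

tcs = ptb.read_matrix("data.tsv")
spec = ptb.parse_query("q.json")
ranked = ptb.run_probabilistic(spec, tcs)      # top-m (id, log-likelihood)
members = ptb.run_deterministic(spec, tcs)     # with spec.mode = "deterministic"
hmm = ptb.compile_hmm(spec, tcs)               # inspect states/durations
```

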