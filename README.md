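# pbwtkit

Compression and exact match finding for phased haplotype panels with the
**positional Burrows–Wheeler transform (PBWT)**.

## The problem

Given M phased haplotype sequences over N biallelic variant sites
(alleles coded 0/1), population geneticists repeatedly need the long
exact matches inside the panel — candidate segments identical by descent
(IBD) — and the best matches of new sequences against a reference panel,
as seeds for imputation and phasing. Scanning all pairs costs O(NM²);
hidden-Markov-model matching is heavier still. pbwtkit targets analysts
working with panels of thousands to hundreds of thousands of haplotypes
who need these matches, and compact storage of the panels, at O(NM) cost.

## The transform

For each position k, sort the sequences by their **reversed prefixes**
x[k−1], x[k−2], …, x[0] (ties broken by sequence index). Two arrays are
carried forward in a single O(NM) sweep:

* the positional prefix array `a_k` — the permutation realising that
  sort, and
* the divergence array `d_k` — `d_k[i]` is the smallest j such that the
  sorted neighbours `a_k[i−1]` and `a_k[i]` agree on every site in
  [j, k), with sentinel `d_k[0] = k`.

The alleles of column k read in `a_k` order form the PBWT column `y_k`.
Because linkage disequilibrium makes sequences with similar prefixes
carry the same next allele, `y_k` consists of long runs and compresses
far better than the raw matrix. An FM-index-style extension function
`w_k(i, allele)` built from cumulative zero/one counts maps sorted
boundaries from k to k+1, so the whole structure can be stored as
run-length-encoded columns plus sparse `(a, d)` checkpoints and replayed
anywhere.

Matching falls out of the sorted order: maximally matching sequences are
adjacent in it, so

* all locally maximal matches of length ≥ L (`long_matches`),
* all **set-maximal** matches — each sequence's locally maximal matches
  not contained in a longer match to anyone (`set_maximal_matches`), and
* set-maximal matches of new query sequences against an indexed panel
  (`query_set_maximal`, and the joint-sweep `query_batch`)

are found in time O(NM + output), or for indexed queries essentially
independent of M.

## Worked example

```python
import pbwtkit as pk

params = pk.CopyingModelParams(M=200, N=2000, founders=12, seed=7)
panel = pk.simulate_copying_panel(params)          # LD-structured panel
index = pk.build_index(panel)                      # one O(NM) sweep
print(pk.size_stats(index, raw_text=pk.raw_text_baseline(panel)))

ms = pk.set_maximal_length_stats(panel.iter_columns(), panel.M, panel.N,
                                 panel.positions)
print(f"set-maximal match intervals : {ms.n_intervals}")
print(f"mean length                 : {ms.mean_bp/1e3:.1f} kb")
```

prints

```
total container bytes   106365
column payload bytes    18652
checkpoint bytes        37684
site table bytes        34004
payload bytes per site  9.326
gzip baseline bytes     56410
gzip / PBWT ratio       3.02
set-maximal match intervals : 1989
mean length                 : 255.4 kb
```

The run-length-encoded PBWT columns (18.7 kB) undercut gzip of the raw
0/1 text (56.4 kB) threefold even on this small panel, and the panel's
1989 distinct set-maximal segments average 255 kb. A chimeric query
built from sequences 0 and 5 locates its two donors exactly:

```python
z = panel.sequence(0).copy()
z[1000:] = panel.sequence(5)[1000:]
for m in pk.query_set_maximal(index, z):
    print(m)
# Match(seq_a=0, seq_b=0,   start=0,    end=1000)
# Match(seq_a=0, seq_b=188, start=0,    end=1000)   (tied partner)
# Match(seq_a=0, seq_b=5,   start=1000, end=2000)
```

A command-line interface covers the same ground:
`pbwtkit encode | decode | stats | longmatch | maxmatch | query |
batchquery | simulate | filter` (see `pbwtkit --help`).

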