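# Methods

## Data model and coordinates

A panel is an M×N matrix of 0/1 alleles: M phased haplotype sequences
over N biallelic sites in genome order. Sites are 0-based and every
interval is half-open [k1, k2). Missing data and multi-allelic sites
are rejected at construction: the algorithms are exact-match machinery,
and exactness is their premise. Approximate matching across genotyping
error is out of scope; the intended pattern is to use exact matches as
seeds and extend or join them by direct comparison downstream.

## The sweep

At position k the sequences are ordered by reversed prefixes
(x[k−1] … x[0], ties by original index; at k = 0 all prefixes tie, so
`a_0` is the identity and `d_0` is all zeros). One step to k+1 is a
stable partition of `a_k` by the allele at k, with the divergence array
updated by a running maximum: scanning sorted entries, the largest
divergence value seen since the previous member of the same allele
class is the new neighbour's match start (initialised to the sentinel
k+1, which also covers the boundary between the 0-block and 1-block,
where the neighbours necessarily differ at k). Divergence values are
stored as absolute start positions, not lengths, because the update
rule and all match reports use starts directly.

Two invariants pin the semantics down and are property-tested against
brute force on seeded panels: `a_k` equals a stable sort of reversed
prefixes, and `d_k[i]` equals the direct backwards comparison of the
sorted neighbours. A consequence of biallelic data worth noting: when
`d_k[i] > 0`, the two neighbours carry alleles 0 and 1 at `d_k[i]−1`.

The step kernel (and the set-maximal scan below) is compiled with
numba; the same kernel backs the public per-step API, `build_index`,
the streaming matchers and the large-scale statistics sweep, so there
is exactly one implementation of the update rule.

## Matching

**Long matches.** At each k, maximal blocks of sorted positions with
divergence ≤ k−L hold exactly the pairs matching on ≥ L sites up to k;
pairs whose alleles differ at k end there and are reported with their
true start (the running maximum of divergence values between the two
block positions). Matches reaching N are flushed at the final boundary.
Each locally maximal match is reported exactly once, at its end.

**Set-maximal matches.** For target i at position k the best possible
match start is e = min(d[i], d[i+1]) (virtual d[M] = k). The scan walks
outward collecting neighbours tied at e and aborts as soon as a tied
neighbour shares the target's current allele — the match then extends
past k, so nothing ending at k is set-maximal for i. The abort makes
the scan cost proportional to reported output; the linear-time bound
assumes bounded groups of sequences identical over the whole region
(identical pairs are reported to every partner at the final flush).

**Queries.** Against a built index, the query state (e, f, g) — all
sorted panel positions in [f, g) match the query on [e, k) — advances
by two rank lookups per site on the run-length structure of column k.
When the interval empties, the matches ending at k are reported (they
are automatically left-maximal, because e is minimal); the state then
rebases at the query's insertion boundary at k+1, recomputing e by
direct backwards comparison against the two sorted neighbours through
the index's inverse-extension (select) walk, and re-expanding the tied
block the same way. Sequence identities for reporting are resolved by
walking forward to the next stored `a` checkpoint. Per-query work is
therefore proportional to the matches found and their lengths, not to
M, once the index is resident.

**Batch queries.** A joint sweep over panel ∪ queries restricts the
neighbour scan to panel members when locating the nearest partners
(running divergence maxima skip over interleaved queries), so queries
never suppress one another's matches and the output multiset equals the
union of per-query runs — an equality asserted on every test instance.

**Centered blocks.** The bidirectional variant reads, at sweep position
k+L2, maximal sorted blocks with divergence ≤ k−L2 without splitting by
the current allele: groups pairwise identical on [k−L2, k+L2).
Singleton blocks are reported too, so the output partitions the panel.

**Oracles.** The brute-force implementations (`naive_*`) apply the
definitions literally — per-pair mismatch scanning plus a containment
filter for set-maximality — and define correct output; every fast path
is tested for multiset equality against them on ≥100 seeded panels.

## Average set-maximal match length

When a target's set-maximal interval is shared by a block of tied
partners, one Match record per partner is emitted but the statistic
treats the block as a single shared segment: the headline "mean
set-maximal match length" averages over distinct (target, interval)
events. Per-record averaging is also reported
(`MatchLengthStats.mean_bp_per_record`); it is dominated by short
intervals that tie across many partners and is several-fold smaller.
Base-pair length of [k1, k2) is pos[k2−1] − pos[k1].

## Codec and container

PBWT columns are byte-token run-length encoded: top bit = allele, bits
6–5 = unit (00→1, 01→64, 10→2048, 11 reserved), bits 4–0 = unit count
1–31. Runs decompose greedily largest-unit-first, making the encoding
canonical (bit-exact tests). A run of 64 < r < 2048 typically costs
2 bytes; the worst case is 4 (a remainder of 63 single units needs
three 1-unit tokens). Zero counts and the reserved unit never occur in
valid payloads and are rejected on decode, as are length mismatches.

The `.pbwt` container is fixed little-endian: magic `PBWT1`, header
(M, N, checkpoint interval C, flags), optional site table, per-column
records (c_k, payload length, payload), checkpoint records, and a
CRC-32 of the body. Full `a` and `d` arrays are stored at every k ≡ 0
(mod C) and at k = N — `d` as zigzag-varint deltas — so any
intermediate state is ≤ C replay steps away. C defaults to 64;
reconstruction equality with the uninterrupted sweep is tested for
C ∈ {1, 5, 16, 64}. Rank/select on a column is answered from its run
structure in O(log runs); no O(NM) rank tables are ever materialised.
32-bit fields cap M and N below 2^32, ample for the target scale.

## Synthetic panels

The built-in generator is a Li–Stephens-style copying model: founders
drawn from a 1/f-weighted site-frequency spectrum (f copies of the
derived allele with probability ∝ 1/f — the neutral shape, not claimed
exact), then each haplotype m copies earlier ones left-to-right,
switching template and flipping alleles at per-site rates that scale as
founders/m. The scaling matters: with more potential templates a new
haplotype finds a closer one, which is what makes PBWT run counts — and
payload bytes per site — grow sublinearly in M, the property real
LD panels show. Defaults (founders 20, switch 0.02, flip 0.002, 1 kb
mean spacing) give panels whose adjacent-site LD clearly exceeds
100-site LD and whose payload beats gzip at a few hundred sequences.
What the model does not emulate: recombination-rate variation, gene
conversion, genotyping error, population structure. Passing tests on
these panels therefore demonstrate algorithmic correctness and the
qualitative compression mechanism, not calibrated population-genetic
quantities — those come from coalescent simulation.

Headline measures use msprime: one neutral population, Ne = 10,000,
mutation and recombination 2.5×10⁻⁸ per bp per generation (scaled
rates 0.001/bp), 20 Mb, 100,000 haplotypes — the regime the reported
compression and matching figures refer to. Subsets of a coalescent
sample are coalescent samples, so the 1000- and 10,000-haplotype
measures subsample one parent simulation: the compression measure keeps
all parent sites (many monomorphic in the subset, as in the original
subset experiments), the matching measure keeps segregating sites
(monomorphic sites cannot alter match intervals). These sizes run in
about two minutes on one core; the 100,000-sequence compression-factor
experiment itself is deliberately out of desk scale.

## Numerical and design choices

* k = 0 state: identity permutation, zero divergences; sentinels
  d_k[0] = k and virtual d_k[M] = k.
* Matches ending at N are flushed with the k = N state; interior
  reports require an allele mismatch at the end position.
* Output ordering is by ending position, then sorted-block position;
  consumers must not rely on more. Long-match pairs are canonicalised
  (smaller index first); set-maximal records are directional
  (target, partner).
* Empty panels (M = 0 or N = 0) build explicit empty indexes; single-
  sequence panels carry sentinel-only divergence arrays; set-maximal
  matching requires M ≥ 2 by contract.
* The CLI converts a base-pair length threshold to sites with the
  region-average density (N−1)/(span) — an approximation, adequate when
  site density is roughly uniform.
* VCF input aborts on unphased heterozygous or missing genotypes by
  default (`drop_unphased=True` drops offending sites instead);
  unphased homozygotes are accepted since their haplotypes are
  unambiguous. Multi-allelic and non-SNV records are skipped with a
  logged count.
* The site-major text reader takes the token immediately before the
  allele string as the position column and ignores other leading
  fields; the coalescent adapter rescales unit-interval positions to
  base pairs and bumps rounding collisions to keep positions strictly
  increasing.

## Known limitations

* Binary alleles only; no missing data, no error tolerance.
* The linear-time set-maximal bound degrades when large groups of
  sequences are identical across the whole region.
* Indexed queries decode column run structures on demand; repeated
  query workloads benefit from the per-column cache but a cold pass
  over a huge index is I/O-bound rather than M-bound.
* The per-interval averaging convention for match-length statistics is
  this package's definition; per-record means differ substantially when
  tie blocks are large, and comparisons across tools should check which
  convention is in use.
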