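"""Reference-free differential detection: find SNVs private to one sample
by kmer content alone.

Sample A is a plain diploid; sample B carries 10 extra homozygous SNVs.
The kmer stage counts 25-mers in both read sets, keeps B's reads that carry
well-supported kmers absent from A, and re-calls variants on the survivors
— no alignment of the full libraries needed."""

import wgadiff as w

genome = w.simulate_genome(30_000, 0.5, seed=21)
haps_a, _ = w.plant_variants(genome, 0, seed=22)
haps_b, extra = w.plant_variants(genome, 10, het_fraction=0.0,
                                 min_spacing=500, seed=23)
kit = w.CaptureKit(name="whole", targets=((genome.name, 0, genome.length),),
                   efficiency=1.0)
cfg = w.ReadSimConfig(depth=30.0, base_error_rate=0.001, seed=24)
reads_a = w.simulate_reads(haps_a, kit, cfg)
reads_b = w.simulate_reads(haps_b, kit, w.ReadSimConfig(
    depth=30.0, base_error_rate=0.001, seed=25))

result = w.differential_call(
    (list(reads_a.reads1), list(reads_a.reads2)),
    (list(reads_b.reads1), list(reads_b.reads2)),
    {genome.name: genome.sequence}, w.FilterConfig(), w.CallParams())

b_pass = [c for c in result.calls_b if c.is_pass]
recovered = {c.key for c in b_pass} & extra.keys()
print(f"unique 25-mers: A-specific {result.n_unique_a}, "
      f"B-specific {result.n_unique_b}")
print(f"reads retained: A {result.stats_a.n_retained}/{result.stats_a.n_input}, "
      f"B {result.stats_b.n_retained}/{result.stats_b.n_input}")
print(f"B-specific PASS calls: {len(b_pass)}; "
      f"{len(recovered)}/{len(extra.keys())} planted extras recovered")
a_pass = [c for c in result.calls_a if c.is_pass]
print(f"A-specific PASS calls (should be ~0): {len(a_pass)}")
print()
print("Each extra SNV creates up to k=25 sample-unique kmers, so only reads")
print("overlapping a true difference survive the filter; shared sequence —")
print("and with it shared mapping artifacts — never reaches the caller.")
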