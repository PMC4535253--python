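"""The central comparison: gDNA vs amplified wgaDNA from the same person,
analyzed map-first and with the kmer differential filter.

Discordant SNVs between the two libraries are amplification (or pipeline)
artifacts by construction — the underlying truth is identical.  The kmer
route should attribute a large share of the map-first discordance to
alignment, mirroring the drop from tens of discordant calls to a few."""

import dataclasses

import wgadiff as w

genome = w.simulate_genome(40_000, 0.5, seed=31)
haps, truth = w.plant_variants(genome, 120, 0.5, 60, seed=32)
kit, _ = w.define_capture_kits(genome, 4, 4_000, 1.0, seed=33, min_gap=1_000)
ref = {genome.name: genome.sequence}
cfg = w.ReadSimConfig(depth=30.0, base_error_rate=0.001)

gdna = w.simulate_reads(haps, kit, dataclasses.replace(cfg, seed=34))
wga = w.apply_wga(haps, w.WgaProfile.default_mda(), kit,
                  dataclasses.replace(cfg, seed=35))

res_g = w.call_pipeline(list(gdna.reads1), list(gdna.reads2), ref)
res_w = w.call_pipeline(list(wga.reads1), list(wga.reads2), ref)
pg = [c for c in res_g.calls if c.is_pass]
pw = [c for c in res_w.calls if c.is_pass]

site = w.compare_sets(pg, pw, mode="site")
print(f"map-first: {site.n_a} gDNA vs {site.n_b} wgaDNA PASS SNVs, "
      f"{site.n_intersection} shared, "
      f"{site.n_only_a}+{site.n_only_b} discordant "
      f"(site concordance {100 * site.concordance:.1f}%)")

strata = w.depth_stratified(pg, pw, (1, 10, 20, 30), "site",
                            depth_a=res_g.depth, depth_b=res_w.depth)
for s in strata:
    conc = "NA" if s.concordance is None else f"{100 * s.concordance:.1f}%"
    print(f"  >={s.threshold:>2}X in both: {s.n_positions_retained:>3} sites "
          f"retained ({100 * s.fraction_retained:.0f}%), concordance {conc}")

diff = w.differential_call(
    (list(gdna.reads1), list(gdna.reads2)),
    (list(wga.reads1), list(wga.reads2)),
    ref, w.FilterConfig(), w.CallParams())
n_kmer = sum(1 for c in diff.calls_a + diff.calls_b if c.is_pass)
print(f"kmer-filtered: {n_kmer} discordant SNVs "
      f"(vs {site.n_discordant} map-first)")
print()
print("The gap between the two discordance counts is the share of apparent")
print("amplification artifacts that the reference-free route exposes as")
print("alignment noise rather than real sequence difference.")
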