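"""Count true restriction sites by exact in silico digestion.

Plants a known number of SbfI sites in a synthetic genome, digests the
genome, and compares the observed site coordinates with the planted
truth.  The digest is the ground-truth proxy every prediction is judged
against: each site yields two RAD loci in a sequencing experiment.
"""

import radsites as r

genome = r.simulate_genome(r.GenomeSimSpec(length=500_000, contig_count=2, seed=11))
genome, planted = r.plant_sites(genome, r.SBFI, n_sites=25, seed=12)

site_map = r.digest_resource(genome, r.SBFI)
print(f"planted sites : {len(planted)}")
print(f"digest count  : {site_map.total_count}")
for contig in genome:
    starts = site_map.starts(contig)
    print(f"  {contig}: {len(starts)} sites, first at {starts[0] if starts else '-'}")

observed = sorted((c, s) for c, recs in site_map.sites.items() for s, _ in recs)
print(f"coordinates match planted truth: {observed == planted}")
print()
print("The background is certified site-free, so the digest recovers exactly")
print("the planted coordinates; on real assemblies the count plays the role")
print("of the best available estimate of the true number of RAD cut sites.")
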