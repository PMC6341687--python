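"""Classify mapped loci against cut sites and compare all estimates.

Runs the complete validation chain on one synthetic dataset: predict
site counts from composition, count true sites by digestion, assemble a
RAD catalogue, map locus consensus sequences back to the genome,
classify each against the known cut-site coordinates (scenarios I-V)
and consolidate everything in one summary table.
"""

import radsites as r

genome = r.simulate_genome(r.GenomeSimSpec(length=600_000, seed=31))
genome, sites = r.plant_sites(genome, r.SBFI, n_sites=60, seed=32)
site_map = r.sites_to_map(sites, r.SBFI)
length = sum(len(s) for s in genome.values())

# composition-model predictions on the post-planting genome
profile = r.profile_composition(genome)
predictions = {
    model: r.expected_site_count(
        r.total_site_probability(profile, r.SBFI, model), length, r.SBFI
    )
    for model in r.MODELS
}

# empirical estimate: assemble, map, classify
spec = r.RadSimSpec(n_individuals=8, error_rate=0.001, digestion_prob=0.9,
                    snp_prob=0.3, seed=33)
reads, _truth = r.simulate_radseq(genome, sites, spec)
empirical = {}
for params in (r.AssemblyParams(3, 2, 1), r.AssemblyParams(2, 2, 1)):
    catalogue = r.assemble_cohort(reads, params)
    report = r.classify_catalogue(catalogue, genome, site_map)
    empirical[f"m{params.m}_M{params.M}_n{params.n}"] = report.empirical_site_count

print(report.summary_frame().T.to_string(header=False))
print()
summary = r.summary_report(
    predictions={"genome": predictions},
    insilico_count=site_map.total_count,
    empirical_counts=empirical,
)
print(summary.to_string(index=False))
print()
print("Scenario I-III sites carry the empirical count; IV/V groups are loci")
print("mapping away from any cut site and are discarded as artefacts.  The")
print("summary table lines up model predictions, the in silico digest and")
print("the assembly-derived counts on one scale.  Composition models see")
print("only the background k-mer spectrum, so they stay near the ~9 sites a")
print("random 600 kb sequence would carry; the 60 planted sites are an")
print("enrichment the digest and the mapped RAD loci both recover exactly.")
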