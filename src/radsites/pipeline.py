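"""End-to-end convenience wrappers tying the pipeline stages together."""

from __future__ import annotations

from typing import Mapping, Sequence

from .assembly import AssemblyParams, RadCatalogue, assemble_individual, build_catalogue
from .digest import RestrictionSiteMap
from .enzymes import Enzyme
from .mapping import LocusAlignment, ScenarioReport, classify_sites, exact_map_loci


def assemble_cohort(
    reads_by_individual: Mapping[str, Sequence[tuple[str, str]]],
    params: AssemblyParams,
    read_length: int | None = None,
) -> RadCatalogue:
    """Assemble every individual and build the cross-individual catalogue."""
    per_individual = [
        (ind, assemble_individual(reads, params, individual=ind, read_length=read_length))
        for ind, reads in reads_by_individual.items()
    ]
    return build_catalogue(per_individual, params)


def map_catalogue(
    catalogue: RadCatalogue, genome: dict[str, str]
) -> list[LocusAlignment]:
    """Map catalogue consensus sequences with the built-in exact mapper."""
    return exact_map_loci(catalogue.consensus_fasta(), genome)


def classify_catalogue(
    catalogue: RadCatalogue,
    genome: dict[str, str],
    site_map: RestrictionSiteMap,
    enzyme: Enzyme | None = None,
    tolerance: int = 2,
) -> ScenarioReport:
    """Exact-map the catalogue and classify loci against the site map."""
    alignments = map_catalogue(catalogue, genome)
    return classify_sites(alignments, site_map, enzyme=enzyme, tolerance=tolerance)
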