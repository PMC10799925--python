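"""Defense-island mining and marker prevalence.

Generates annotated toy genomes whose defense systems are separated by
gaps in and out of the 1-15 kb window, mines the inter-system regions,
extracts intervening proteins, and computes how often a rare planted
marker gene co-occurs with the BREX system. The worked example at the end
uses the literature counts (21 carrier genomes of 7308 with BREX).
"""

from phagescan import islands
from phagescan import synthetic_data as sd
from phagescan.io_formats import DefenseSystemAnnotation

fx = sd.gen_defense_genomes(sd.GeneratorConfig(seed=2, genomes=120,
                                               marker_prevalence=0.05))
regions = islands.find_intersystem_regions(fx.systems, fx.genes)
inter = islands.extract_intervening_proteins(
    regions, {g.protein_id: g for g in fx.genes})
print(f"{len(fx.systems)} systems on {fx.truth_total_brex} genomes")
print(f"{len(regions)} inter-system regions with gaps in [1000, 15000] bp")
print(f"{len(inter)} unique intervening proteins to screen")

prev = islands.prevalence(fx.systems, fx.marker_carriers, "BREX_type_3")
print(f"planted marker prevalence: {prev.carriers}/{prev.total}"
      f" = {prev.percent}%")

# the published worked example: 21 of 7308 BREX genomes carry the marker
systems = [DefenseSystemAnnotation(f"g{i}", "c", "BREX_type_3", 1, 10, "+",
                                   ["x"]) for i in range(7308)]
prev = islands.prevalence(systems, {f"g{i}" for i in range(21)},
                          "BREX_type_3")
print(f"worked example: {prev.carriers}/{prev.total} = {prev.percent}%")
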