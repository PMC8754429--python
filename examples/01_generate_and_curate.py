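"""Generate a BRENDA-like kinetic extract and curate it into reactions.

The generator emits raw database-style rows (including mutant entries and
organisms missing from the growth-temperature table); curation filters to
wild type, matches organisms to T_Growth, aggregates repeated measurements
by median and keeps reactions with variants from >= 2 organisms.
"""

from coldcomp import (
    KineticSimConfig,
    curate,
    generate_kinetic_dataset,
    read_growth_temperatures,
    read_kinetic_entries,
)

config = KineticSimConfig(n_reactions=300, seed=42)
entries_df, t_growth_df, truth = generate_kinetic_dataset(config)

entries, read_report = read_kinetic_entries(entries_df)
t_table = read_growth_temperatures(t_growth_df)
reactions, report = curate(entries, t_table)

print(f"rows read             : {read_report.n_rows}")
print(f"wild-type entries     : {report.n_wild_type}")
print(f"matched to T_Growth   : {report.n_t_growth_matched}")
print(f"values in reactions   : {report.n_values_in_reactions}")
print(f"reactions (>=2 orgs)  : {report.n_reactions}")
print(f"distinct organisms    : {report.n_organisms}")
print(f"T_Growth range        : {report.t_growth_min_C:.0f}-{report.t_growth_max_C:.0f} C")

# Each count is one stage of the curation funnel: every input row ends up
# either rejected (mutant / unmatched organism) or inside exactly one
# reaction.  The reaction count equals the generator's design because mutant
# and stray rows are injected on top of the core reactions.
assert report.n_reactions == config.n_reactions
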