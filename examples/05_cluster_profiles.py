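"""Group accessions by trait profile with ward.D2 / Manhattan clustering.

Genotype means per regime are z-scored per trait, clustered with Ward's
criterion on Manhattan distances (the ward.D2 convention), and cut into
three groups labelled I (highest overall profile) to III (lowest) —
group I is where a breeder looks for high-performing parents.
"""

from trialqg import bluegrass_like_spec, cluster_accessions, generate_trial

table = generate_trial(bluegrass_like_spec(seed=11))

for regime in ("control", "drought"):
    means = table.genotype_means(regime=regime)
    res = cluster_accessions(means, n_groups=3)
    sizes = res.groups.value_counts().sort_index()
    print(f"\n{regime}: group sizes {dict(sizes)}")
    print("group trait means:")
    print(res.group_means.round(1).to_string())
# Group I accessions have the highest standardized means across every trait;
# crossing group I x group III parents maximizes segregation for mapping.
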