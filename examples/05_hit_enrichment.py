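"""Fisher-exact enrichment of an annotation among screening hits.

Given a hit list (e.g. putative compound targets) and a detected-proteome
background, each annotation term is tested with a 2x2 Fisher exact test and
BH-adjusted across terms — the standard way to ask "are ATP-binding proteins
over-represented among my hits?".
"""

import lipmap as lm

background = {f"prot{i}" for i in range(1000)}
hits = {f"prot{i}" for i in range(40)}
annotation = {
    # 30 of 40 hits are ATP binders, vs 70 of 960 non-hits
    "ATP binding": {f"prot{i}" for i in range(30)}
    | {f"prot{i}" for i in range(200, 270)},
    "RNA binding": {f"prot{i}" for i in range(500, 600)},
}

result = lm.fisher_enrichment(hits, background, annotation)
for row in result.itertuples():
    print(f"{row.term:12s} a={row.a:3d} odds={row.odds_ratio:7.2f} "
          f"p={row.p_value:.2e} q={row.q_value:.2e}")
# "ATP binding" shows a large odds ratio and tiny q-value (planted signal);
# "RNA binding" does not overlap the hits and stays non-significant.
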