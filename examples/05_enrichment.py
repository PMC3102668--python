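"""Gene-set over-representation with Fisher's exact test and enrichment ratio.

Re = (m/n) / (M/N) measures how over-represented a term of M genes (universe
N) is among n DE genes containing m members; significance is the one-sided
hypergeometric tail with a chi-squared check alongside and BH FDR across terms.
"""

from dgetag import GeneSetCollection, enrichment_ratio, fisher_enrich

# worked example: 5 of 10 DE genes fall in a 10-gene term, universe 100
print("Re(m=5, n=10, M=10, N=100) =", enrichment_ratio(5, 10, 10, 100))

universe = {f"g{i}" for i in range(100)}
terms = {
    "MUSCLE_DEV": {f"g{i}" for i in range(10)},           # planted target
    "METABOLISM": {f"g{i}" for i in range(40, 70)},
    "RANDOM": {f"g{i}" for i in range(55, 95)},
}
coll = GeneSetCollection(terms=terms, universe=universe)
de_genes = {f"g{i}" for i in range(5)} | {"g77", "g20", "g33", "g90", "g41"}

res = fisher_enrich(de_genes, coll)
print()
print(res[["term", "m", "n", "M", "N", "Re", "p_fisher", "fdr_q",
           "significant"]].to_string(index=False, float_format=lambda v: f"{v:.3g}"))

# MUSCLE_DEV holds 5 of the 10 DE genes but only 10% of the universe
# (Re = 5), so its Fisher p is small; the other terms sit near Re = 1.
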