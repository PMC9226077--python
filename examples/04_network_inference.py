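"""Infer molecule-taxon networks and check them against the planted truth.

Runs the full inference chain — prevalence filter, SparCC correlations on
the joint composition, |rho| >= 0.3 thresholding into signed bipartite
networks — on a synthetic dataset with known consumer (negative) and
producer (positive) links, and reports precision and recall.
"""

from edtia import conet, synthetic

design = synthetic.make_design()
library = synthetic.gen_formula_library(200, seed=1)
effects = synthetic.PeakEffects(link_strength=1.2, n_consumer_links=10,
                                n_producer_links=10, links_per_taxon=3)
peaks, truth = synthetic.gen_peak_table(design, library, effects=effects, seed=2)
otus = synthetic.gen_otu_table(design, 100, coupling=truth, seed=3,
                               coupling_strength=1.2)

fpeaks, dropped_m = conet.prevalence_filter(peaks)
fotus, dropped_t = conet.prevalence_filter(otus)
print(f"prevalence filter (>50% of samples): kept {fpeaks.shape[1]} molecules "
      f"({len(dropped_m)} dropped), {fotus.shape[1]} genera "
      f"({len(dropped_t)} dropped)")

corr = conet.sparcc_correlations(fpeaks, fotus, n_bootstrap=20, seed=4,
                                 n_permutations=0)
for sign, links in [("negative", truth.consumer_links),
                    ("positive", truth.producer_links)]:
    net = conet.build_bipartite(corr, threshold=0.30, sign=sign)
    found = set(zip(net.edges["molecule"], net.edges["genus"]))
    tp = len(found & set(links))
    print(f"{sign} network: {len(net.edges)} edges, "
          f"precision {tp / max(len(found), 1):.2f}, "
          f"recall {tp / len(links):.2f} against planted links")
print("Negative edges are putative decomposition links (taxon up, molecule "
      "down); positive edges putative production links.")
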