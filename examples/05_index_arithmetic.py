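"""Worked arithmetic: PSIRI from reported index triples, Akaike weights from
a reported delta-AIC column.

Diet studies usually print FO, PW and PN per prey group and the model
selection tables print delta AIC; both downstream quantities are pure
arithmetic on those values, so reported tables can be checked directly.
"""

import dietstat as ds
from dietstat.stomach_weight_model import akaike_table

# typical reported triples for a copepod-dominated pelagic diet
triples = {
    "copepods": (81.3, 72.9, 97.3),
    "euphausiids": (40.1, 18.6, 1.3),
    "large_crustaceans": (21.2, 42.1, 9.8),
    "small_crustaceans": (7.6, 16.1, 4.4),
    "chaetognaths": (1.0, 16.2, 0.8),
    "ova": (13.6, 0.2, 1.2),
}
print("group                FO%    PW%    PN%   -> PSIRI%")
for group, (fo, pw, pn) in triples.items():
    print(f"{group:18s} {fo:6.1f} {pw:6.1f} {pn:6.1f}   -> {ds.psiri(fo, pw, pn):5.2f}")

print("\nModel ranking from a reported delta-AIC column {8.92, 0, 1, 4.4}:")
tab = akaike_table(deltas=[8.92, 0.0, 1.0, 4.4])
print(tab[["model", "delta_AIC", "weight", "in_confidence_set"]]
      .round(3).to_string(index=False))
print("\nWeights are normalized relative likelihoods exp(-dAIC/2); the 95%\n"
      "confidence set is the smallest weight-ordered subset reaching 0.95.")
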