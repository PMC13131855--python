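"""Summarize regional regression findings by lobe and hemisphere.

Loads the bundled example table of uncorrected-significant perivascular-
space findings and reports, for each model term, what fraction of the
significant region-level effects falls in each lobe and how they split
across hemispheres.
"""

from csfmarkers import summarize_effects_by_lobe
from csfmarkers.datasets import load_pvs_findings_example

findings = load_pvs_findings_example()
summary = summarize_effects_by_lobe(findings, alpha=0.05)

for term, entry in summary.items():
    print(f"{term}: {entry['n_significant']} significant region effects")
    if entry["n_significant"]:
        pct = ", ".join(f"{lobe} {p}%" for lobe, p in entry["lobe_percent"].items())
        hemi = entry["hemisphere_counts"]
        print(f"  by lobe: {pct}")
        print(f"  hemispheres: L={hemi['L']}, R={hemi['R']}")
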