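"""Alpha diversity of the clone libraries, published and synthetic.

Computes OTU richness, Good's coverage, Chao1, ACE, Shannon and Simpson
for the published per-OTU clone counts and for the recovered synthetic
libraries, writing results/diversity_published.tsv and
results/diversity_synthetic.tsv.
"""

from pathlib import Path

import pandas as pd

from gctherm import datasets
from gctherm.diversity import alpha_summary

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    table = datasets.clone_table()
    samples = {
        label: table.loc[table["label"] == label, "count"].tolist()
        for label in table["label"].unique()
    }
    published = alpha_summary(samples)
    published.to_csv(RESULTS / "diversity_published.tsv", sep="\t", index=False)
    print("Alpha diversity of the published clone libraries:")
    print(published.round(3).to_string(index=False))

    otu_dir = RESULTS / "otu_tables"
    if otu_dir.exists():
        synth = {}
        for path in sorted(otu_dir.glob("otus_*.tsv")):
            df = pd.read_csv(path, sep="\t")
            synth[path.stem.removeprefix("otus_")] = df["count"].tolist()
        synthetic = alpha_summary(synth)
        synthetic.to_csv(RESULTS / "diversity_synthetic.tsv", sep="\t", index=False)
        print("\nAlpha diversity of the recovered synthetic libraries:")
        print(synthetic.round(3).to_string(index=False))
    else:
        print("\n(no synthetic OTU tables found; run analysis/02_trim_cluster.py for those)")


if __name__ == "__main__":
    main()
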