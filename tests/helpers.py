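import pandas as pd

from phototf.sites import BindingSiteSet


def make_sites(rows, cluster="TOY/1", length=None):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "score"])
    L = length or int((df["end"] - df["start"]).iloc[0])
    return BindingSiteSet(cluster, L, df)
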