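"""Score ingestion primitives: masked-marginal log-odds, long-protein
windowing, and dataset-wide min-max normalization."""

from famvar.scoring import (EsmQuery, esm_masked_marginal, esm_window,
                            minmax_normalize)

# Language-model score: log P(mut) - log P(wt) at the masked position;
# more negative = more deleterious.
q = EsmQuery(sequence="MKTAYIAKQR", position_in_window=5, wt_aa="Y",
             mut_aa="C", logp_wt=-1.0, logp_mut=-3.0)
print(f"masked-marginal log-odds: {esm_masked_marginal(q):+.2f}")

# Long proteins are windowed to the model's 1022-residue input cap.
seq = "A" * 2000
window, idx = esm_window(seq, position=1000)
print(f"2000-residue protein -> window of {len(window)}, variant at index {idx}")

# Raw scores are min-max normalized over the whole dataset so 1 is the most
# deleterious; reversed-orientation raw scores are flipped via 1 - norm(X).
normed, stats = minmax_normalize([-8.2, -6.1, -2.0], "lower_is_pathogenic")
print(f"raw ESM scores [-8.2, -6.1, -2.0] -> normalized "
      f"{[round(x, 3) for x in normed.tolist()]} (min={stats.min}, max={stats.max})")
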