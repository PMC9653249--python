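"""Segment a token stream into rapid sequences and tabulate composition.

Uses the packaged deterministic fixture stream that realizes the published
length-by-composition contingency table: 377 detected sequences of which
18 contain a token with unknown duration and are excluded, leaving 359.
"""

from gesturelaws import (
    filter_complete,
    length_composition_table,
    segment_sequences,
    table1_fixture_tokens,
)

tokens = table1_fixture_tokens()
sequences = segment_sequences(tokens, gap_threshold_s=1.0)
kept, n_excluded = filter_complete(sequences)
table = length_composition_table(kept)

print(f"{len(sequences)} sequences detected; {n_excluded} excluded "
      f"(unknown durations); {len(kept)} analysed")
print("length  same  diff  total")
for r in table.rows:
    same = "-" if r.n_same_type is None else r.n_same_type
    diff = "-" if r.n_different_type is None else r.n_different_type
    print(f"{r.length:>6}  {same!s:>4}  {diff!s:>4}  {r.n_total:>5}")
share = table.n_same_total / table.n_multi
print(f"multi-token sequences: {table.n_multi}; "
      f"same-type share {table.n_same_total}/{table.n_multi} = {share:.0%}")
# A same-type share well below half means repetition of a single gesture
# type is the exception: most multi-gesture sequences mix types.
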