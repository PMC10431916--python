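# Data dictionary

All interchange files are UTF-8 CSV with a header row. Floating-point
values are written with shortest round-trip representation, so
write → read → write is byte-identical.

## Session table (one row per choice trial)

| column | type | values / units | notes |
|---|---|---|---|
| `participant_id` | str | | unique per subject |
| `age_years` | float | years | constant within subject |
| `age_group` | str | `children` / `adolescents` / `adults` | derived: <13 / <18 / ≥18 |
| `block` | int | 1..10 | strictly increasing within subject |
| `block_difficulty` | str | `easy` / `hard` | easy: reward triple 0.8/0.5/0.2; hard: 0.7/0.5/0.3 |
| `trial` | int | 1..15 | within-block position, strictly increasing |
| `stim_left`, `stim_right` | str | stimulus ids | both belong to the block's 3-stimulus set; left ≠ right |
| `prob_left`, `prob_right` | float | [0, 1] | the displayed options' true reward probabilities |
| `choice` | str | `left` / `right` / `missed` | |
| `outcome` | str | `win` / `loss` / `none` | `none` iff `choice == missed` |
| `rt_sec` | float | (0, 4] seconds, or empty | empty iff missed; < 0.2 marks a fast guess |

Validation (applied on read and write): required columns present, value
domains as above, outcome present iff a choice was made, probabilities in
[0, 1], positive response times, rows ordered by (`block`, `trial`)
within participant. Violations raise an error naming the offending rows.

## Memory table (one row per memory probe)

| column | type | notes |
|---|---|---|
| `participant_id` | str | |
| `block` | int | the probed block |
| `option_1` .. `option_5` | str | the five-alternative array: the block's three stimuli, one previously seen stimulus from a different block, one never-shown stimulus |
| `correct_id` | str | the block's highest-probability stimulus |
| `response_id` | str | the (simulated) response |

## Ground-truth parameter table (one row per simulated subject)

`participant_id`, `age_years`, `age_group`, `group`, `model`, plus one
`true_<parameter>` column per generating parameter (`true_beta_sm`,
`true_eta`, and `true_novelty_bias` / `true_w_unc` where the generating
model has them).

## Feature table (one row per trial; output of the `features` command)

Per-option belief features computed *before* the trial's outcome, with
beliefs reset at block starts and lifetime presentation counts global:
`ev_left`/`ev_right` (beta mean), `unc_left`/`unc_right` (beta variance),
`nov_left`/`nov_right` (variance of Beta(presentations+1, 1));
left-minus-right differences `d_ev`, `d_unc`, `d_nov`; chosen-option
features `ev_chosen`, `unc_chosen`, `nov_chosen` (empty on missed
trials); and `similar_ev` (boolean, `|d_ev| < 0.05`, strict).
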