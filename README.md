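# oshprior

Multi-criteria prioritization of occupational-safety (labor protection)
measures. The package turns an alternatives × criteria performance matrix
into a defensible priority order through a five-stage pipeline:

1. **Objective weighting** — four data-driven schemes (Shannon entropy,
   CRITIC dispersion × conflict, a removal-effect scheme, and a
   reciprocal-sum impact-loss scheme) derive criterion weights from the
   matrix itself, then a Bonferroni mean fuses them into one vector.
2. **MARCOS ranking** — each alternative's weighted-sum score
   `Q_i = Σ_j w_j r_ij` is benchmarked against appended ideal and
   anti-ideal reference rows through the ratios `λ⁺ = Q_i/Q⁺` and
   `λ⁻ = Q_i/Q⁻`, combined into a compromise utility `U_i`.
3. **Benchmarking** — TOPSIS, VIKOR, EDAS, WASPAS and PROMETHEE-II run
   with the same weights; Kendall τ (tau-a) and Spearman ρ quantify
   inter-method agreement.
4. **Sensitivity** — one-at-a-time weight perturbations
   (`ω′_h = ω_h ± ε`, remainder redistributed equally) re-rank the
   problem under 2·m·|ε-levels| scenarios and tabulate rank frequencies.
5. **Consensus** — Borda (`n − rank` points) and Copeland (pairwise
   majority wins) aggregation plus a Stability Index
   `SI_i(k) = #{scenarios with A_i in top-k} / #scenarios` produce the
   final order.

It is written for OSH analysts and decision-modelers who need a
transparent, reproducible priority ranking of safety interventions —
engineering controls, administrative controls, PPE, training, digital
monitoring — under conflicting criteria such as affordability,
risk-reduction effectiveness, compliance, worker acceptance,
sustainability, and ease of implementation. A complete expert-scored
case study of that exact shape (5 alternatives × 6 benefit criteria on a
1–9 scale) ships with the package.

## Worked example

```python
>>> import oshprior as op
>>> problem = op.labor_protection_problem()        # bundled 5×6 matrix
>>> weights = op.CASE_STUDY_FUSED_WEIGHTS          # fused criterion weights
>>> table = op.marcos_rank(problem, weights)
>>> [float(round(u, 4)) for u in table.utilities]
[0.594, 0.6967, 0.7124, 0.681, 0.5954]
>>> [int(r) for r in table.ranks]
[5, 2, 1, 3, 4]
```

A3 (personal protective equipment) attains the highest compromise
utility, 0.7124, on a scale anchored by the anti-ideal row at 0.4487 and
the ideal row at 0.8443; A2 (administrative controls) is second at
0.6967. Aggregating all six methods:

```python
>>> rankings = op.run_rankers(problem, weights)
>>> report = op.final_consensus(rankings)
>>> report.order()
('A3', 'A2', 'A4', 'A1', 'A5')
>>> report.borda_scores['A3'], report.copeland_scores['A3']
(22.0, 4.0)
```

A3 wins 22 of the maximum 24 Borda points and beats every other
alternative in a majority of pairwise contests (Copeland +4). The same
pipeline runs from the shell:

```sh
oshprior run --out results --format csv-bundle   # full pipeline, one CSV per stage
oshprior rank --matrix my_matrix.csv --weights auto
oshprior sensitivity --eps 0.05,0.10,0.15 --policy include
```

Use `--weights auto` to compute and fuse the four objective weight
vectors for your own matrix, or `--weights file:w.csv` to inject one.

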