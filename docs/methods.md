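# Methods

Definitions, procedures and parameter choices for `foldswitch-bench`.
Section order follows the pipeline: similarity scoring, classification,
confidence auditing, the two intervention front ends (MSA masking and
template preparation), and the synthetic generator used for validation.

## 1. Structural similarity

### Superposition and RMSD

`similarity.kabsch` computes the optimal proper rigid transform between
paired point sets by SVD of the cross-covariance matrix, flipping the sign
of the smallest singular direction whenever the raw solution would be a
reflection; chiral structures are never mirrored. Backbone RMSD is taken
over all N, CA, C, O atoms present in both partners of the region, after a
Kabsch fit on those same atoms.

### TM-score

Predictions carry the target's own sequence, so residue correspondence is
positional and the TM-score reduces to a maximization over rigid
superpositions of the region CA atoms:

    TM = max_sup (1/L) * sum_i 1 / (1 + (d_i/d0)^2),
    d0(L) = max(0.5, 1.24 (L-15)^(1/3) - 1.8)

with `L` the reference region length. The maximization has three stages:

1. **Fragment seeding.** Every contiguous CA fragment of lengths `L`,
   `L/2` and `L/4` (minimum 4) seeds a Kabsch superposition.
2. **Iterative refinement.** Each seed alternates between selecting the
   residue pairs within a distance cutoff and re-superposing on them. The
   cutoff starts at `d0 + 1` Å and shrinks by 0.5 Å (floor 3.0 Å) whenever
   the selected set stops changing; the best TM seen is kept.
3. **Simplex polish.** The refinement optimizes a moving surrogate (the
   selected-pair RMSD), which can stall a hair from the true optimum. The
   top three candidates therefore get a derivative-free Nelder–Mead ascent
   of the TM objective itself over the six rigid-body parameters (rotation
   vector delta applied via the Rodrigues formula, plus translation
   delta). Stage 3 is an extension of the classical two-stage scheme,
   added because the contract here is *maximization*: without it the
   fragment search and an independent 500-restart random-superposition
   oracle disagree by up to ~0.007 at heavy noise; with it they agree to
   < 0.005 on every tested case (see `tests/test_acceptance.py` and
   `scripts/acceptance.py`).

`frame="local"` (default) fits superpositions on the region itself;
`frame="global"` fits one superposition on the whole chain and evaluates
the TM sum over the region. Local is the default because fold-switching
is assessed on the region: a model whose region matches conformation B
should score as such even when its flanks sit in the conformation-A
frame. Global is kept as an option for whole-chain sanity checks.

## 2. Classification

A model is assessed against both experimental conformations over their
respective regions. With regional scores `tm1` (against Fold1) and `tm2`
(against Fold2):

- label **Fold1** if `tm1 > 0.6` and `tm1 >= tm2`;
- label **Fold2** if `tm2 > 0.6` and `tm2 > tm1`;
- label **Other** otherwise — including the boundary `tm = 0.6` exactly,
  which is deliberately *not* a match (the rule is strict inequality), and
  the tie `tm1 == tm2 > 0.6`, which goes to Fold1.

**Fold1** is defined per protein as the conformation matched by the
majority of the default five predictions (conformation A when unset or
tied); **Fold2** is the other. **Dual success** for a protein means at
least one model labelled Fold1 and at least one labelled Fold2; the
benchmark success rate is the fraction of proteins with dual success.

## 3. Confidence auditing

Per-residue pLDDT is read from the CA B-factor column and validated to
[0, 100]. The **confident fraction** of a model is the fraction of
residues with pLDDT ≥ 70 (the conventional "confident" floor). Models are
binned by confident fraction `f` into nested pools:

| pool   | rule       |
|--------|------------|
| All    | every model |
| Medium | f ≥ 0.7    |
| Good   | f ≥ 0.8    |
| High   | f ≥ 0.9    |

Pools nest (All ⊇ Medium ⊇ Good ⊇ High) rather than partition, because
the question is "what survives a quality filter at this strictness", and
each stricter filter acts on the output of the looser one.

**Reranking** sorts models by descending confident fraction, breaking ties
by descending mean pLDDT and then by model id (total and deterministic).
Top1/Top10/All selections are taken from this order.

**Census.** For each protein, pool and conformation, the census counts
models (`n_models`, written as Nij) and flags the conformation as
*predicted* for that protein/pool iff Nij ≥ 1.

**Depletion test.** If a conformation is identified for `k_all` of `n`
proteins over all models but only `k_high` of `n` within the High pool,
the null hypothesis is that high-confidence identification occurs at the
overall rate `p0 = k_all / n`, and the evidence for depletion is the
exact one-sided lower tail

    P(X <= k_high), X ~ Binomial(n, p0).

`binom_lower` evaluates each term with `scipy.special.gammaln` in log
space and sums the terms in ascending order, so tails around 1e-4 — the
regime the reference counts live in — carry no cancellation error;
`tests/test_acceptance.py` checks exact agreement with full 2^n outcome
enumeration. The null reconstruction uses `p0 = k_all/n` (a plug-in rate,
not a hypergeometric draw) because the High pool is not a fixed-size
sample from the protein set: membership is determined by the models, and
the question is whether high-confidence identification behaves like the
overall identification rate.

## 4. MSA masking (modified SPEACH)

For a structure, an a3m alignment of its sequence and a fold-switching
region, the generator slides an 11-residue window in steps of 1 over the
region and, for each window:

- finds every residue with a heavy atom within 4.0 Å of any window
  residue's heavy atom, excluding the window itself and residues within 4
  sequence positions of the nearest window residue (local contacts are
  trivial; the targets are tertiary contacts);
- masks the alignment columns of the window and those contacts to `A`
  (alanine) in every row except the query. Gap characters and lowercase
  insertion states are preserved exactly; only match-state residues
  change.

One masked a3m per window is written together with a manifest recording
the window bounds, the masked contact positions, and the expected number
of models per masked alignment (15: five models times three seeds, the
usual downstream protocol).

## 5. Template preparation and fold ranking

Templates for rescoring are prepared by:

1. **Standardization.** MSE → MET (SE → SD), SEC → CYS (SE → SG).
2. **Sidechain stripping.** Only N, CA, C, O, CB are kept.
3. **Glycine CB.** Glycines receive an ideal CB placed 1.521 Å from CA at
   tetrahedral geometry with L-amino-acid chirality (improper dihedral
   N–CA–C–CB ≈ −122.6°), since downstream template featurization expects a
   CB on every residue.

Preparation is idempotent. Pairs are **eligible** if both conformations
cover at least half of the common sequence (`min_frac = 0.5`) and no gap
inside the fold-switching region exceeds 5 residues (`max_gap = 5`) —
long interior gaps make regional TM-scores incomparable between the two
conformations.

Rescoring combines template agreement and predictor confidence into the
composite

    composite = tm_out_template * ptm * (pLDDT / 100)

a product rather than a sum so that failure of any one signal (template
ignored, low pTM, low pLDDT) zeroes the score; it is monotone in each
argument. `rank_folds` declares the conformation with the higher
composite the ground state, breaking ties by pLDDT and declaring
`undetermined` on a full tie. Pairs whose true ground state is `both`
are excluded from accuracy (either answer is defensible), and accuracy is
the fraction correct among determined, non-excluded verdicts.

## 6. Synthetic generator

Validation needs structures whose true labels are known. The generator
builds backbones by natural-extension-of-reference-frame chaining with
ideal geometry (N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å; angles
111.2°/116.2°/121.7°; ω = 180°) and secondary-structure dihedrals: helix
(−57, −47), strand (−139, 135), coil (per-residue draws from
alpha/beta basins), and a packed beta-hairpin (turn dihedrals
(60, −120)/(−90, 0), chosen by grid search to maximize long-range
heavy-atom contacts — 24 at 4 Å for a 40-mer — so the masking code's
contact rule is actually exercised).

`make_pair` builds two conformations sharing helical flanks, with the
fold-switching region helical in conformation A and extended in B —
the canonical alpha-to-beta switch. Models are drawn from a
Fold1/Fold2/Other mixture: correct models are the corresponding
conformation plus isotropic Gaussian coordinate noise; Other models are
unrelated coil. pLDDT profiles are drawn per model around a
label-dependent confident-fraction target.

Defaults (`ScenarioSpec`): 60-residue chain, region 16–45, mixture
(0.6, 0.3, 0.1), `noise_sigma = 0.4` Å, pLDDT spec Fold1 (0.85, 0.08),
Fold2 (0.55, 0.15), Other (0.80, 0.10).

- `noise_sigma = 0.4` gives correct models a regional TM around 0.8 —
  clearly above the 0.6 threshold yet visibly non-ideal, so the
  classifier is tested away from both the trivial and the boundary
  regimes. Oracle-equivalence stress tests use σ = 1 instead, where the
  TM landscape has competing local optima.
- The pLDDT spec deliberately scores Fold2 models lower: this is the
  regime the confidence audit exists to detect, and the generator's
  mixture and depletion are recovered by the pipeline within binomial
  sampling error (`tests/test_acceptance.py::test_scenario_parameter_recovery`).

**What the generator does and does not emulate.** It emulates the
observable interface of a predictor run — an ensemble of PDB models with
pLDDT in the B-factor column, drawn with a controllable conformation
mixture and confidence bias. It does not emulate a predictor's actual
error modes: noise is isotropic Gaussian (real model error is correlated
along the chain), "Other" models are random coil (real failures are often
compact but wrong), and pLDDT here is drawn from the true label rather
than computed from the coordinates. Conclusions about any real predictor
require real predictions; the generator only validates that the
*measurement machinery* is correct.

## 7. Numerical and interface choices

- Exact binomial tails are computed in log space and summed ascending
  (section 3); no normal approximation anywhere.
- `perturb` adds i.i.d. Gaussian noise per coordinate; its expected RMSD
  from the source is σ√3 (checked by Monte Carlo in the tests).
- Altloc handling keeps the highest-occupancy alternative per atom.
- `truncate_to_common` aligns two sequences by longest-common-subsequence
  dynamic programming and keeps the matched core (minimum 10 residues),
  reporting what was dropped.
- All TSV/JSON outputs are plain text; structures are written as PDB via
  gemmi.

**Build vs buy.** gemmi handles structure I/O; scipy supplies `cdist`,
`gammaln`, `minimize` and rotation sampling; pandas handles tables; click
the CLI. The scientific core — Kabsch with reflection control, the
TM-score maximizer, the classification and depletion logic, the masking
rule, template preparation and the backbone builders — is implemented
here, and validated in the tests against independent implementations
(Biopython's `SVDSuperimposer`, `scipy.stats.binom`, brute-force
random-restart and all-pairs oracles, and full outcome enumeration).

## 8. Limitations

- Positional correspondence assumes predictions of the exact target
  sequence; no structural alignment search is performed.
- The TM maximizer is a local-search scheme with a polish stage; the
  acceptance suite bounds its disagreement with a 500-restart oracle at
  0.005 on the tested regime, not a global-optimality proof.
- The depletion test conditions on the observed overall rate `p0`; it
  does not propagate uncertainty in `p0` itself.
- Synthetic realism limits are listed in section 6.
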