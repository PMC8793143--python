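# forcebind

Quantitative analysis of peptide–mineral adhesion from two complementary
experiments: **single-molecule force spectroscopy** (SMFS, AFM-based) and
**quartz crystal microbalance with dissipation monitoring** (QCM-D).  The
package was built around the hydroxyapatite-binding dodecapeptide
SVSVGMKPSPRP and its alanine-scan derivatives, but every stage is generic.

## Who it is for

Biophysicists processing AFM force–distance retract curves into unbinding
kinetics, and surface scientists converting multi-overtone QCM-D traces into
adsorbed mass and molar surface concentrations.  All inputs are plain
delimited text; all results are JSON/TSV.

## The models

**Tether elasticity.** The stretch preceding each unbinding event follows the
Marko–Siggia worm-like chain interpolation

$$F(x) = \frac{k_BT}{L_p}\left[\frac{1}{4(1-x/L_c)^2} - \frac14 + \frac{x}{L_c}\right],$$

with persistence length $L_p$ and contour length $L_c$ ($k_BT$ = 4.114 pN·nm
at 298 K).

**Unbinding kinetics.** The most probable rupture force depends on the
loading rate $r$ through the Bell–Evans(–Ritchie) relation

$$F(r) = \frac{k_BT}{\chi}\,\ln\!\frac{r\,\chi}{k_{\mathrm{off}}\,k_BT},$$

parameterized by the transition-state distance $\chi$ and the intrinsic
dissociation rate $k_{\mathrm{off}}$.  The dissociation barrier follows from
an Arrhenius relation, $\Delta G = -RT\,\ln(k_{\mathrm{off}}/A)$ with
$A = 10^6$ Hz.

**Adsorbed mass.** Frequency/dissipation shifts of a film under liquid are
modelled with the first-order Voinova (Voigt) small-load expressions at fixed
film density (1100 kg/m³, hydrated-film convention) and inverted per time
point for the areal mass density $h_1\rho_1$; the Sauerbrey relation
$\Delta m = -C\,\Delta f/n$ ($C$ = 17.6 ng cm⁻² Hz⁻¹ at 5 MHz) serves as the
rigid-film limit and fallback.

A synthetic-data module generates both kinds of raw data with known ground
truth — rupture forces drawn from the closed-form Bell–Evans first-passage
distribution, WLC-shaped curves with contact adhesion and noise, and
Langmuir film growth rendered through the Voigt model — so the whole chain
is validated end to end.

## Worked example

Simulate a three-speed SMFS campaign with native-peptide kinetics
($\chi = 0.38$ nm, $k_{\mathrm{off}} = 0.0433$ s⁻¹) and analyse it:

```bash
forcebind simulate smfs -o curves --seed 9 --speeds 300,1000,3000 \
    --curves-per-speed 40 --specific-probability 0.9
echo "mpf_min_events: 20" > cfg.yaml
forcebind analyze smfs curves -o kinetics.json --config cfg.yaml
```

prints

```
chi = 0.366 +/- 0.001 nm; k_off = 0.0635 /s; F(10 nN/s) = 107.3 pN; dG = 41.1 kJ/mol
```

i.e. the full chain (rupture detection → specificity QC → most-probable-force
per experiment → Bell–Evans regression → barrier) recovers the generating
transition-state distance within a few percent, the reference force at
10 nN/s, and the ~42 kJ/mol barrier.  The same for a QCM-D adsorption run
(Langmuir growth to 550 ng/cm², partial wash-off):

```bash
forcebind simulate qcmd -o qcm --seed 4 --stage-times 600,7800,9600
forcebind analyze qcmd qcm/trace.tsv -o adsorption.json --peptide native
```

```
df(include_wash) = -121.7 Hz; total = 368.1 ng/cm^2; conc = 0.297 nmol/cm^2
```

against a ground-truth net density of 389 ng/cm² for this noisy trace.  The
surface concentration divides the areal density by the peptide's average
molecular weight (1241.5 Da for the native sequence).

The peptide library itself:

```bash
forcebind peptides scan -o library   # FASTA + TSV with mw and net charge
```

As a library, the fit-shaped stages are scikit-learn-style estimators
(`BellEvansModel`, `MostProbableForce`, `RuptureDetector`, `VoigtFilmModel`)
with `fit`/`predict`/`get_params`, and every operation is also exposed as a
plain function (`fit_bell_evans`, `most_probable_force`, ...).

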