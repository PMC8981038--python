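# boldsim

Simulated BOLD (blood-oxygen-level-dependent) signals from spiking network
models, computed **on-line** while the network runs.

`boldsim` is aimed at computational neuroscientists who want to relate
mesoscopic spiking network models to fMRI measurements, or to compare
hypotheses about **neurovascular coupling** — which neural signals drive
cerebral blood flow (CBF) and oxygen metabolism (CMRO2). It provides:

* **Hemodynamic models defined as equations.** A small text grammar
  (parameters block + equations block) declares ODE and algebraic variables,
  integrated with forward Euler on a fixed millisecond grid. Input signals
  are read with the accessor `sum(NAME)`.
* **Built-in Balloon models.** The four classic variants (`balloon_CN`,
  `balloon_CL`, `balloon_RN`, `balloon_RL`: classic/revised coefficients ×
  non-linear/linear BOLD equation), a **two-input** Balloon model with
  parallel CBF/CMRO2 drive and viscoelastic venous outflow, and a Davis-model
  extension.
* **A BOLD monitor.** Converts per-neuron *source variables* (firing rate,
  conductances, synaptic currents, or arbitrary arithmetic expressions over
  them) of one or more populations into the model's input signals:
  average over each population → optional baseline normalization
  `(x − B)/B` → scale by the population's share of the region of interest →
  sum across populations.
* **A minimal spiking microcircuit** (Izhikevich regular-spiking and
  fast-spiking neurons, Poisson drive, conductance-based AMPA/GABA synapses
  with log-normal weights, fixed in-degree 10 per projection) that exercises
  six neurovascular-coupling hypotheses (monitors A–F).

## The model

The classic Balloon model couples neural activity to the BOLD signal via a
flow-driving signal $s$ and normalized CBF $f_{in}$:

$$\dot s = \phi\, I_{CBF} - \kappa s - \gamma (f_{in} - 1), \qquad
  \dot f_{in} = s$$

oxygen extraction $E(f_{in}) = 1 - (1-E_0)^{1/f_{in}}$, venous volume $v$ and
deoxyhemoglobin $q$:

$$\dot v = \tfrac{1}{\tau_0}\big(f_{in} - v^{1/\alpha}\big), \qquad
  \dot q = \tfrac{1}{\tau_0}\Big(f_{in}\tfrac{E}{E_0} -
  v^{1/\alpha}\tfrac{q}{v}\Big)$$

and the non-linear BOLD equation
$\mathrm{BOLD} = V_0\,[k_1(1-q) + k_2(1-q/v) + k_3(1-v)]$ with classic
($k_1 = 7E_0,\ k_2 = 2,\ k_3 = 2E_0 - 0.2$) or revised
($k_1 = 4.3\,\nu_0 E_0\,TE,\ k_2 = \varepsilon r_0 E_0\,TE,\ k_3 =
1-\varepsilon$) coefficients.

The two-input variant drives normalized CMRO2 $r$ by a second, faster
damped oscillator, uses $r$ directly in the deoxyhemoglobin balance, and
adds a viscoelastic outflow $f_{out} = v^{1/\alpha} + \tau_{visc}\dot v$ so
the venous balloon recovers slowly. This reproduces the initial dip and a
prolonged post-stimulus undershoot. The Davis extension evaluates
$\Delta\mathrm{BOLD} = M\,[1 - f^{\alpha_D} (r/f)^{\beta_D}]$ alongside.

## Worked example

Drive the default Balloon model with a rectangular input (0 → 0.2 between
5 s and 25 s), exactly the package's reference stimulus:

```python
import boldsim as bs
import boldsim.experiments as ex

model = bs.get_model("balloon_RN")
ss = bs.steady_state(model, {"I_CBF": 0.1})
print(round(ss.values["f_in"], 4))        # 1.246  = 1 + 0.1/gamma

ts = ex.run_artificial_pulse("classic")   # 60 s, dt = 1 ms
t = ts.time
print(f"peak BOLD {ts['BOLD'].max():.4f} at {t[ts['BOLD'].argmax()]/1000:.1f} s")
print(f"post-stimulus undershoot {ts['BOLD'][t > 25_000].min():.4f}")
```

prints

```
1.246
peak BOLD 0.0139 at 11.8 s
post-stimulus undershoot -0.0020
```

i.e. a ~1.4 % BOLD increase peaking ~7 s after stimulus onset, followed by
the characteristic negative undershoot after stimulus offset. The two-input
model under its reference inputs (`ex.run_artificial_pulse("two_input")`,
I_CBF → 0.2 and I_CMRO2 → 0.05) additionally shows the **initial dip**: the
BOLD trace first drops to −0.0008 before rising to its positive peak,
because CMRO2 responds faster than CBF.

Attaching a monitor to a network:

```python
net = bs.build_microcircuit(250, seed=1)           # corE 200, corI 50, Poisson 200
pops = [net.populations["corE"], net.populations["corI"]]
mon = bs.BoldMonitor(bs.MonitorConfig(
    populations=pops, model="balloon_RN",
    mapping={"I_CBF": "syn"},                      # afferent-normalized conductance
    normalize_window=5000.0,                       # 5 s baseline
    recorded_variables=["I_CBF", "f_in", "BOLD"]))
net.attach_monitor(mon)
net.run(2000.0)                                    # settle
mon.start()
net.run(25_000.0)
recordings = mon.get_recordings(dt=net.dt)         # a TimeSeries
```

## Command line

```bash
boldsim artificial --model two_input --plot   # rectangular-input responses
boldsim demo --seed 0                         # two-population noise-step demo
boldsim pulse --seeds 40                      # normalized vs raw monitor
boldsim hypotheses --stimulus sustained       # coupling hypotheses A-F
boldsim scale                                 # microcircuit size table
boldsim simulate config.yaml                  # config-driven run
```

All recordings are written as time-indexed CSV (optionally HDF5), figures
as PNG.

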