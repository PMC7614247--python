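"""Transient dynamics, channel ranking and ablation on the neural-tube
circuit.

Starting near the boundary of the Nkx-high basin, Olig rises transiently
before Nkx takes over — the bulk species (Irx, Pax) store the recent history
of the subnetwork and delay Nkx through memory.  The script compares the
full system, the memoryless QSS reduction and the self-consistent memory
reduction (ZMs); ranks the memory channels by their integrated contribution
along the ZMs trajectory; and re-simulates with only the dominant channels
kept (the rest set to QSS).

Qualitative demonstration on an illustrative parametrization.

Run:  python examples/neural_tube_transient.py
"""

import numpy as np

import memnet as mn


def main():
    model = mn.build_model("neural_tube4", p=0.65)
    part = model.partition
    xs0 = np.array([1.4, 0.3])
    t_end = 40.0
    ts = np.linspace(0, t_end, 9)

    full = mn.integrate_full(model, xs0, t_end, partition=part,
                             bulk_at_qss=True)
    qss = mn.integrate_qss(model, part, xs0, t_end)
    cs = mn.decompose_channels(model, part)
    zms = mn.integrate_zms_channels(cs, xs0, t_end)

    print("t      full(Nkx,Olig)    zms(Nkx,Olig)     qss(Nkx,Olig)")
    for t in ts:
        f = full(t)[:2]
        z = zms(t)
        q = qss(t)
        print(f"{t:5.1f}  {f[0]:6.3f} {f[1]:6.3f}   "
              f"{z[0]:6.3f} {z[1]:6.3f}   {q[0]:6.3f} {q[1]:6.3f}")

    grid = np.linspace(0, t_end, 400)
    ref = full(grid)[:, :2]
    err_zms = np.max(np.abs(zms(grid) - ref))
    err_qss = np.max(np.abs(qss(grid) - ref))
    print(f"\nsup-norm error vs full: zms {err_zms:.4f}, qss {err_qss:.4f}")

    ranking = mn.rank_channels(cs, zms)
    print("\nchannel ranking (source->out_bulk~in_bulk->target):")
    print(ranking.to_frame(species=model.species).to_string(index=False))

    top = ranking.top(2)
    ablated = mn.integrate_zms_channels(cs, xs0, t_end, keep=top)
    err_abl = np.max(np.abs(ablated(grid) - ref))
    print(f"\nkeeping only the top-2 channels: sup-norm error {err_abl:.4f} "
          f"(all channels {err_zms:.4f}, no channels {err_qss:.4f})")


if __name__ == "__main__":
    main()
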