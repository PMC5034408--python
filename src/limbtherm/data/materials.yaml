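# Library of prosthetic liner/socket materials with bench-measured
# thermal time constants (minutes), and liner+socket combinations with
# the time constant observed at the liner-socket interface.
materials:
  - name: Alpha Locking
    kind: liner
    material: co-polymer
    thickness_mm: 6.0
    tau_min: 3.6
  - name: Iceross Comfort
    kind: liner
    material: silicone
    thickness_mm: 6.0
    tau_min: 3.1
  - name: Iceross Original
    kind: liner
    material: silicone
    thickness_mm: 3.0
    tau_min: 2.6
  - name: OttoBock Technogel
    kind: liner
    material: polyurethane
    thickness_mm: 6.0
    tau_min: 2.8
  - name: Pe-lite
    kind: liner
    material: closed cell foam
    thickness_mm: 5.0
    tau_min: 1.6
  - name: stump sock
    kind: sock
    material: terry
    thickness_mm: 0.7
    tau_min: 0.6
  - name: thermoplastic
    kind: socket
    material: co-polymer polypropylene
    thickness_mm: 4.7
    tau_min: 4.0
  - name: thermosetting lay-up
    kind: socket
    material: compound of materials
    thickness_mm: 4.0
    tau_min: 4.1
  - name: carbon fibre lay-up
    kind: socket
    material: compound of materials
    thickness_mm: 4.8
    tau_min: 4.5
combinations:
  - liner: OttoBock Technogel
    socket: thermosetting lay-up
    combo_tau_min: 5.4
  - liner: Iceross Comfort
    socket: carbon fibre lay-up
    combo_tau_min: 5.5
  - liner: Iceross Original
    socket: carbon fibre lay-up
    combo_tau_min: 4.1
  - liner: Iceross Comfort
    socket: thermosetting lay-up
    combo_tau_min: 5.8
  - liner: Alpha Locking
    socket: carbon fibre lay-up
    combo_tau_min: 6.2
  - liner: Pe-lite
    socket: thermoplastic
    combo_tau_min: 6.7
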