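# Default outcome panel: 29 FinnGen-style pain endpoints (names are opaque
# labels; map each to a summary-statistic file in the scan config).
- migraine
- migraine without aura
- migraine with aura
- tension-type headache
- cluster headache
- other headache syndromes
- trigeminal neuralgia
- brachial plexus disorders
- radiculopathy
- sciatica
- low back pain
- dorsalgia
- dorsalgianas
- cervicalgia
- limb pain
- coxarthrosis
- gonarthrosis
- other joint disorders
- arthralgia
- myalgia
- fibromyalgia
- neuralgia and neuritis
- carpal tunnel syndrome
- shoulder lesions
- panniculitis
- abdominal and pelvic pain
- pelvic and perineal pain
- femgenpain
- chronic postprocedural pain
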