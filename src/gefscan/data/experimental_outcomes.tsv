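# Per-variant experimental outcome labels from paired-recording
# electrophysiology (AMPAR-eEPSC amplitude vs untransfected control):
# loss_of_function = no WT-like potentiation; dominant_negative = amplitude
# reduced below control; wt_like = WT-like potentiation.
label	predicted	outcome
E1299W	deleterious	dominant_negative
C1387W	deleterious	loss_of_function
T1430W	deleterious	loss_of_function
A1464W	deleterious	wt_like
T1394A	benign	wt_like
E1304G	deleterious	loss_of_function
Y1318G	deleterious	loss_of_function
Y1383A	deleterious	wt_like
G1453W	deleterious	loss_of_function
S1403F	benign	wt_like
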