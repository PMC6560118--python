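# Synthetic toy dose-factor matrix for a 25 g mouse-like phantom.
# Rows = target organs, columns = source organs; DF in mGy/(MBq h).
# Values are order-of-magnitude realistic for Tb-152 (electron self-dose
# dominated, weak photon cross-fire) but are NOT a published phantom matrix;
# real rodent DF tables are pluggable through the same loader.
# phantom_name = toy-mouse-25g
target,heart,lungs,liver,kidneys,small_intestine,large_intestine,rest_of_body
heart,416.0,4.0,3.0,0.8,0.5,0.4,1.2
lungs,4.0,1194.0,2.5,0.7,0.4,0.3,1.2
liver,3.0,2.5,70.3,2.2,1.8,1.2,1.0
kidneys,0.8,0.7,2.2,330.0,2.0,1.5,1.1
small_intestine,0.5,0.4,1.8,2.0,70.1,3.5,1.0
large_intestine,0.4,0.3,1.2,1.5,3.5,184.0,1.0
rest_of_body,0.9,0.8,0.9,0.9,0.9,0.9,8.26
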