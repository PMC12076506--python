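{
  "version": "1.0",
  "comment": "Hydrogen-bond donor/acceptor SMARTS, equivalent to the default RDKit BaseFeatures definitions for the Donor and Acceptor families.",
  "families": {
    "donor": [
      "[$([N;!H0;v3,v4&+1]),$([O,S;H1;+0]),n&H1&+0]"
    ],
    "acceptor": [
      "[$([O,S;H1;v2;!$([O,S]-*=[O,N,P,S])]),$([O,S;H0;v2]),$([O,S;-]),$([N;v3;!$(N-*=[O,N,P,S])]),n&H0&+0,$([o,s;+0;!$([o,s]:n);!$([o,s]:c:n)])]"
    ]
  }
}
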