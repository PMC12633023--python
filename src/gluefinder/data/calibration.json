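{
 "score_edges": [
  0.6463200115096882,
  0.675403317623614,
  0.6950743477559008,
  0.7163757693207874,
  0.7507955740312786,
  0.8115609058518645,
  0.859039051909786,
  0.9009144634902325,
  0.934721160476959
 ],
 "p_edges": [
  1.6324083015467994e-12,
  1.216106070750015e-09,
  1.3304339452240417e-06,
  0.00022224351637812177,
  0.035361724754731705,
  0.20114585838484825,
  0.36707798801343927,
  0.5592644928320556,
  0.801211830534615
 ],
 "values": [
  [
   0.2608695652173913,
   0.11688311688311688,
   0.11688311688311688,
   0.05172413793103448,
   0.045454545454545456,
   0.030303030303030304,
   0.006024096385542169,
   0.006024096385542169,
   0.006024096385542169,
   0.006024096385542169
  ],
  [
   0.803921568627451,
   0.2608695652173913,
   0.11688311688311688,
   0.11688311688311688,
   0.05172413793103448,
   0.045454545454545456,
   0.030303030303030304,
   0.006024096385542169,
   0.006024096385542169,
   0.006024096385542169
  ],
  [
   1.0,
   0.803921568627451,
   0.2608695652173913,
   0.11688311688311688,
   0.11688311688311688,
   0.05172413793103448,
   0.045454545454545456,
   0.030303030303030304,
   0.006024096385542169,
   0.006024096385542169
  ],
  [
   1.0,
   1.0,
   0.803921568627451,
   0.2608695652173913,
   0.11688311688311688,
   0.11688311688311688,
   0.05172413793103448,
   0.045454545454545456,
   0.030303030303030304,
   0.006024096385542169
  ],
  [
   1.0,
   1.0,
   1.0,
   0.803921568627451,
   0.2608695652173913,
   0.11688311688311688,
   0.11688311688311688,
   0.05172413793103448,
   0.045454545454545456,
   0.030303030303030304
  ],
  [
   1.0,
   1.0,
   1.0,
   1.0,
   0.803921568627451,
   0.2608695652173913,
   0.11688311688311688,
   0.11688311688311688,
   0.05172413793103448,
   0.045454545454545456
  ],
  [
   1.0,
   1.0,
   1.0,
   1.0,
   1.0,
   0.803921568627451,
   0.2608695652173913,
   0.11688311688311688,
   0.11688311688311688,
   0.05172413793103448
  ],
  [
   1.0,
   1.0,
   1.0,
   1.0,
   1.0,
   1.0,
   0.803921568627451,
   0.2608695652173913,
   0.11688311688311688,
   0.11688311688311688
  ],
  [
   1.0,
   1.0,
   1.0,
   1.0,
   1.0,
   1.0,
   1.0,
   0.803921568627451,
   0.2608695652173913,
   0.11688311688311688
  ],
  [
   1.0,
   1.0,
   1.0,
   1.0,
   1.0,
   1.0,
   1.0,
   1.0,
   0.803921568627451,
   0.2608695652173913
  ]
 ]
}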